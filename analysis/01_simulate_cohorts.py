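#!/usr/bin/env python
"""Generate the desk-scale synthetic study: discovery GWAS summary
statistics for the four smoking phenotypes and a target cohort of
schizophrenia cases, unaffected first-degree relatives and controls.

Writes the fixture files (summary stats, dosages in both dialects,
phenotypes, truth, config, manifest) under scratch/fixtures; downstream
scripts consume them. Deterministic in --seed.
"""

import argparse
from pathlib import Path

from transprs.simulate import SimulationConfig, generate_fixture_set

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-variants", type=int, default=20_000)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "fixtures")
    args = ap.parse_args()

    cfg = SimulationConfig(n_variants=args.n_variants, seed=args.seed)
    print(f"simulating: {cfg.n_variants} variants in blocks of "
          f"{cfg.block_size}, discovery n={cfg.n_discovery}, target "
          f"{cfg.n_cases}/{cfg.n_relatives}/{cfg.n_controls} "
          f"(SCZ/FR/HC) at prevalence {cfg.prevalence}, rg={cfg.rg}")
    manifest = generate_fixture_set(cfg, args.out)
    print(manifest.to_string(index=False))
    print(f"wrote {len(manifest)} files to {args.out}")


if __name__ == "__main__":
    main()
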