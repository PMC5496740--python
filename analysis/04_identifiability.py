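"""Flux non-identifiability from pool snapshots, and its time-course remedy.

Writes the fixed-pools scenario table (fluxes 12, 24, 6 all reproducing
pools AP=3, AL=6), the flat flux profile likelihood on steady-state-only
counts (CSV + figure), and a small BafA-transient fit simulation showing
that time-resolved counts do recover (J, beta, gamma).
"""

import argparse
from pathlib import Path

import pandas as pd

from autoflux import PipelineConfig, default_config, run_identifiability_demo


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/identifiability"))
    args = ap.parse_args()

    cfg = PipelineConfig(
        generator=default_config(seed=args.seed), output_dir=str(args.out)
    )
    report = run_identifiability_demo(cfg, timecourse=True, make_figure=True)
    print("scenario table (identical pools, three fluxes):")
    print(report["scenario_table"].to_string(index=False))
    prof = report["profile"]
    print(f"profile log-likelihood spread over flux grid "
          f"[{prof['flux'].min():.1f}, {prof['flux'].max():.1f}]: "
          f"{prof['loglik'].max() - prof['loglik'].min():.2e} "
          f"(flat: pool snapshots carry no flux information)")
    rec = pd.read_csv(Path(report["output_dir"]) / "recovery_summary.csv")
    print("BafA-transient fit recovery (truth J=12, beta=1.333, gamma=1):")
    print(rec[["influx_J", "beta", "gamma"]].median().round(3).to_string())


if __name__ == "__main__":
    main()
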