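#!/usr/bin/env python
"""Recover the conformational FRET states of single and tandem SBDs.

Simulates 10^4-burst µs-ALEX datasets for the apo (E* = 0.58) and
glutamine-saturated (E* = 0.74) SBD2 states and the inter-domain tandem
state (E* = 0.33, stoichiometry selection 0.25-0.6), fits one covariant
bivariate Gaussian to each, and tabulates the fitted means against the
generating values.  Writes results/fret_states.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from smalex import FluorophoreState
from smalex.pipeline import single_state_mu


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cases = [
        ("SBD2 apo", 0.58, 0.50, None),
        ("SBD2 + glutamine (closed)", 0.74, 0.50, None),
        ("inter-domain tandem apo", 0.33, 0.45, (0.25, 0.6)),
    ]
    rows = []
    for label, e_true, s_true, s_sel in cases:
        r = single_state_mu(
            FluorophoreState(label, e_true, s_true),
            n_bursts=10_000, seed=args.seed, s_selection=s_sel,
        )
        rows.append(
            {"dataset": label, "e_true": e_true, "mu_e_fit": r["mu_e"],
             "mu_s_fit": r["mu_s"], "w_e": r["w_e"],
             "n_bursts_fitted": r["n_bursts"],
             "abs_error": abs(r["mu_e"] - e_true)}
        )
    df = pd.DataFrame(rows)
    args.out.mkdir(exist_ok=True)
    df.to_csv(args.out / "fret_states.csv", index=False)

    print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    worst = df.abs_error.max()
    print(f"\nAll three state means recovered; worst |error| = {worst:.4f} "
          f"({'within' if worst < 0.01 else 'OUTSIDE'} +-0.01).")


if __name__ == "__main__":
    main()
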