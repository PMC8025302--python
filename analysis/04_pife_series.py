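#!/usr/bin/env python
"""PIFE read-out of domain proximity: stoichiometry shifts vs linker length.

The printed mean stoichiometries of the Cy3-labelled SBD2 construct series
(0.291 single domain, 0.306 tandem, 0.339 five-residue linker deletion)
imply donor brightness factors via the odds transform; this driver simulates
the series with those factors, refits the stoichiometry means, tabulates the
ΔS* shifts and the linker trend, and runs the Cy3B-style alpha=1 null
control.  Writes results/pife_shifts.csv and results/pife_null.csv.
"""

import argparse
from pathlib import Path

from smalex import derive_pife_factor, null_control
from smalex.pife import linker_trend
from smalex.pipeline import pife_construct_series

PRINTED = {"single SBD2": 0.291, "tandem SBD1-2": 0.306, "SBD1-d5-SBD2": 0.339}


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    base = PRINTED["single SBD2"]
    specs = [
        {"label": label, "s_app": base, "e_app": 0.61,
         "pife_alpha": derive_pife_factor(base, s_printed),
         "linker_delta": delta}
        for (label, s_printed), delta in zip(PRINTED.items(), (0, 0, -5))
    ]
    shifts = pife_construct_series(specs, "single SBD2", seed=args.seed)
    shifts["s_printed"] = list(PRINTED.values())
    shifts["abs_error"] = (shifts.mean_s - shifts.s_printed).abs()

    null_specs = [dict(s, pife_alpha=1.0) for s in specs]
    null_shifts = pife_construct_series(null_specs, "single SBD2",
                                        seed=args.seed + 1)
    report = null_control(null_shifts)

    args.out.mkdir(exist_ok=True)
    shifts.to_csv(args.out / "pife_shifts.csv", index=False)
    null_shifts.to_csv(args.out / "pife_null.csv", index=False)

    cols = ["construct", "s_printed", "mean_s", "delta_s", "alpha", "abs_error"]
    print(shifts[cols].to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    trend = linker_trend(shifts)
    print(f"\nLinker trend: dS*/deleted residue = {trend['slope']:.4f} "
          f"+- {trend['stderr']:.4f}")
    print(f"Cy3B-like null control: max |dS*| = {report['max_abs_delta_s']:.4f} "
          f"(PIFE detected: {report['pife_detected']})")
    print(f"Worst recovery error vs printed means: {shifts.abs_error.max():.4f}")


if __name__ == "__main__":
    main()
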