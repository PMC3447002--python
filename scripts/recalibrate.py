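#!/usr/bin/env python
"""Regenerate the shipped calibration constants.

Re-derives (1) the default motility parameters from the speed / motility
coefficient targets and (2) the steady-state exit power law, and prints
the values frozen in ``paracortex.motility.DEFAULT_MOTILITY`` and
``paracortex.trafficking.CALIBRATED_POWER_A/B``. The exit-law stage runs
dozens of multi-day simulations (expect ~15 min).

    python scripts/recalibrate.py --seed 2024 [--skip-exits] [--beta]
"""

from __future__ import annotations

import argparse

import numpy as np

from paracortex.motility import calibrate_motility
from paracortex.trafficking import calibrate_beta, calibrate_exit_constants


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=2024)
    parser.add_argument("--skip-exits", action="store_true")
    parser.add_argument("--beta", action="store_true",
                        help="also recalibrate beta(K_E) (slow)")
    args = parser.parse_args()

    params = calibrate_motility(15.0, 55.0, rng=np.random.default_rng(args.seed))
    print(f"motility: p0 = {params.p0:.4f}, kappa = {params.kappa:.4f}, "
          f"p_reorient = {params.p_reorient}")

    if not args.skip_exits:
        a, b, table = calibrate_exit_constants(
            rng=np.random.default_rng(args.seed)
        )
        print(table.to_string(index=False))
        print(f"exit power law: N_E * T_res = {a:.4f} * N^{b:.4f}")

    if args.beta:
        coeffs, table = calibrate_beta(rng=np.random.default_rng(args.seed))
        print(table.to_string(index=False))
        print(f"beta(K_E) = {coeffs[0]:.4f} K^2 + {coeffs[1]:.4f} K + {coeffs[2]:.4f}")


if __name__ == "__main__":
    main()
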