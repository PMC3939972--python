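"""One-off calibration of the regularity weight -> windowed ApEn mapping.

Sweeps the mixture weight rho over the monotone region of the curve, runs
several independent full-length subjects per grid point, and prints the
constants to freeze into ``eegpipe.synthetic``.  The mapping is computed
once at build time so cohort generation never runs a calibration loop.

Run from the repository root:

    python scripts/calibrate_regularity.py
"""

import numpy as np

from eegpipe.complexity import ApEnParams, apen
from eegpipe.synthetic import _subject_signal

FS = 200.0
DURATION = 120.0
N = int(FS * DURATION)
WINDOW = 400
STEP = 200
REPS = 6
RHO_GRID = np.round(np.arange(0.40, 0.981, 0.04), 2)


def mean_windowed_apen(x: np.ndarray, params: ApEnParams) -> float:
    vals = [
        apen(x[i : i + WINDOW], params).value
        for i in range(0, len(x) - WINDOW + 1, STEP)
    ]
    return float(np.mean(vals))


def main() -> None:
    params = ApEnParams()
    rng = np.random.default_rng(20260929)
    means = []
    for rho in RHO_GRID:
        per_rep = [
            mean_windowed_apen(
                _subject_signal(rng, float(rho), N, FS, "pink"), params
            )
            for _ in range(REPS)
        ]
        means.append(np.mean(per_rep))
        print(f"rho={rho:.2f}  apen={means[-1]:.4f}  (rep sd {np.std(per_rep):.4f})")

    print("\n_CALIBRATION_RHO = np.array(")
    print("    [" + ", ".join(f"{r:.2f}" for r in RHO_GRID) + "]")
    print(")")
    print("_CALIBRATION_APEN = np.array(")
    print("    [" + ", ".join(f"{m:.4f}" for m in means) + "]")
    print(")")


if __name__ == "__main__":
    main()
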