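"""Regenerate the frozen healthy-A540 mixture defaults.

Solves the two-component truncated-normal mixture against the three cohort
constraints (class mean 0.59, SD 0.27, P(A540 <= 0.74) = 0.81), verifies the
solution with a 10^6-draw Monte Carlo, and prints the parameters that are
frozen in ``chondrohsi.phantom.HEALTHY_A540_MIXTURE``. Also reports the
damaged-class tail mass P(A540 > 0.74) of TN(1.18, 0.48, lower 0).

Run from the repository root:  python scripts/calibrate_defaults.py
"""

from __future__ import annotations

import numpy as np

from chondrohsi.phantom import TruncNormSpec, calibrate_generator


def main() -> None:
    mix = calibrate_generator()
    mean, sd = mix.moments()
    p = float(mix.cdf(np.asarray(0.74)))
    print("solved healthy-A540 mixture:")
    for w, c in zip(mix.weights, mix.components):
        print(f"  weight {w:.8f}  TN(mean={c.mean:.8f}, sd={c.sd:.8f}, lower=0)")
    print(f"analytic: mean={mean:.6f} sd={sd:.6f} P(<=0.74)={p:.6f}")

    rng = np.random.default_rng(0)
    n = 10**6
    comp = rng.random(n) < mix.weights[0]
    draws = np.where(
        comp,
        mix.components[0].ppf(rng.random(n)),
        mix.components[1].ppf(rng.random(n)),
    )
    print(
        f"Monte Carlo (n=10^6): mean={draws.mean():.4f} sd={draws.std():.4f} "
        f"P(<=0.74)={(draws <= 0.74).mean():.4f}"
    )

    damaged = TruncNormSpec(1.18, 0.48)
    print(
        "damaged TN(1.18, 0.48, lower 0): "
        f"P(>0.74)={1.0 - float(damaged.cdf(np.asarray(0.74))):.4f}"
    )


if __name__ == "__main__":
    main()
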