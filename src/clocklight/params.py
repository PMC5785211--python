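"""Fitting bounds and reference parameter sets for the dusk-cluster models.

``BOUNDS`` is the box used for bounded least-squares fitting. Units:
B (basal transcription rate), beta (max transcription rate) and alpha
(decay/dilution rate) are in normalized expression per hour; K (the
coefficient of activation/repression) is in normalized expression
units; H (the Hill coefficient) is dimensionless.

``REFERENCE_FITS`` lists best-fit parameter sets for the Early, Middle
and Late dusk clusters under each model variant, together with the
reported fit error (square root of the summed squared deviations).
They serve as the synthetic-data generator's defaults and as ground
truth for parameter/trajectory-recovery harnesses. The degenerate
"RpaB-only Middle" fit (decay rate unresolved) is omitted.
"""

from __future__ import annotations

#: Box constraints per parameter kind: (lower, upper).
BOUNDS: dict[str, tuple[float, float]] = {
    "H": (0.0, 7.0),
    "beta": (0.0, 80.0),
    "alpha": (0.0, 80.0),
    "B": (0.0, 10.0),
    "K": (0.0, 1.0),
}

#: Model-variant vocabulary. Feedback variants name the source cluster
#: and whether it activates or represses the target.
VARIANTS = (
    "rpaA_only",
    "rpaB_only",
    "joint",
    "feedback:Early:activation",
    "feedback:Early:repression",
    "feedback:Middle:activation",
    "feedback:Middle:repression",
    "feedback:Late:activation",
    "feedback:Late:repression",
)

# Each row: (variant, cluster, B, beta, alpha, K_A, H_A, K_B, H_B, K_Y, H_Y, error)
_ROWS = [
    ("rpaA_only", "Early", 0.71, 37.54, 72.71, 0.71, 6.76, None, None, None, None, 0.85),
    ("rpaB_only", "Early", 0.37, 24.03, 78.62, None, None, 0.37, 0.78, None, None, 1.01),
    ("joint", "Early", 0.35, 51.28, 37.76, 0.35, 4.19, 0.8, 2.5, None, None, 0.41),
    ("feedback:Middle:activation", "Early", 0.01, 55.85, 30.01, 0.01, 0.3, 0.87, 2.38, 0.06, 2.47, 0.37),
    ("feedback:Middle:repression", "Early", 0.67, 58.69, 38.89, 0.67, 6.96, 0.62, 2.47, 0.96, 7.0, 0.24),
    ("feedback:Late:activation", "Early", 0.2, 35.87, 19.03, 0.2, 4.43, 0.98, 3.35, 0.05, 6.15, 0.38),
    ("feedback:Late:repression", "Early", 0.75, 69.34, 42.68, 0.75, 6.22, 0.59, 3.53, 0.71, 2.39, 0.21),
    ("rpaA_only", "Middle", 0.79, 37.95, 63.0, 0.79, 6.76, None, None, None, None, 0.86),
    ("joint", "Middle", 1.0, 57.46, 25.97, 1.0, 4.96, 0.52, 4.12, None, None, 0.29),
    ("feedback:Early:activation", "Middle", 0.8, 23.73, 22.19, 0.8, 6.96, 0.49, 4.53, 0.21, 6.35, 0.32),
    ("feedback:Early:repression", "Middle", 0.73, 71.08, 39.24, 0.73, 5.14, 0.53, 6.58, 0.74, 0.88, 0.35),
    ("feedback:Late:activation", "Middle", 0.18, 78.63, 76.5, 0.18, 6.09, 0.33, 2.64, 0.16, 1.55, 0.16),
    ("feedback:Late:repression", "Middle", 0.68, 31.02, 17.98, 0.68, 3.34, 0.57, 6.79, 1.0, 0.0, 0.44),
    ("rpaA_only", "Late", 0.96, 39.82, 64.37, 0.96, 6.7, None, None, None, None, 0.78),
    ("rpaB_only", "Late", 0.05, 0.0, 0.0, None, None, 0.05, 0.68, None, None, 0.79),
    ("joint", "Late", 0.95, 77.65, 67.1, 0.95, 7.0, 0.48, 5.9, None, None, 0.5),
    ("feedback:Early:activation", "Late", 0.99, 23.93, 20.01, 0.99, 5.8, 0.4, 6.95, 0.18, 6.77, 0.53),
    ("feedback:Early:repression", "Late", 0.76, 59.81, 18.43, 0.76, 6.22, 0.69, 6.13, 0.47, 3.12, 0.29),
    ("feedback:Middle:activation", "Late", 0.37, 27.3, 16.09, 0.37, 3.72, 0.01, 3.46, 0.91, 6.23, 0.22),
    ("feedback:Middle:repression", "Late", 0.86, 25.1, 14.46, 0.86, 6.92, 0.48, 7.0, 1.0, 0.0, 0.52),
]

_FIELDS = ("B", "beta", "alpha", "K_A", "H_A", "K_B", "H_B", "K_Y", "H_Y")

#: {(variant, cluster): {"B": ..., ..., "error": ...}}
REFERENCE_FITS: dict[tuple[str, str], dict[str, float | None]] = {
    (variant, cluster): dict(zip(_FIELDS, values)) | {"error": err}
    for variant, cluster, *values, err in _ROWS
}

#: The best-scoring (lowest-error) feedback topology per cluster.
BEST_FEEDBACK_VARIANT = {
    "Early": "feedback:Late:repression",
    "Middle": "feedback:Late:activation",
    "Late": "feedback:Middle:activation",
}
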