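"""Central analysis thresholds.

Every tunable cutoff used by the pipeline lives in one namespace so that a run
is fully described by a single :class:`Thresholds` instance plus a seed.

Provenance of the defaults:

* ``tau`` — a tumor (or core) is called double-positive for a marker pair when
  at least this fraction of its cells co-stain for both markers.  Default 0.20,
  the study's published cutoff.
* ``ci_cutoff`` — combination-index value separating synergy from antagonism;
  1.0 is the standard Chou–Talalay interpretation.
* ``ci_additive_band`` — half-width of the band around 1.0 reported as
  "additive" rather than forcing a synergy/antagonism call on noise.
  Analysis choice, not a published value.
* ``delta`` — minimum Bliss excess (fraction-affected scale) for a pair to
  count as over-additive in one cell line during screen nomination.  The
  underlying criterion — combined kill beyond what independent action of the
  two agents predicts — is qualitative; delta = 0.10 is this package's
  operationalization and is configurable.
* ``epsilon`` — fraction-affected clipping bound for the median-effect logit
  transform; points at fa=0 or fa=1 carry no information on the logit scale.
* ``n_boot`` — bootstrap replicates for heterogeneity confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Thresholds:
    tau: float = 0.20            # double-positive cutoff on co-positive fraction [published]
    delta: float = 0.10          # Bliss-excess margin for nomination [analysis choice]
    ci_cutoff: float = 1.0       # CI < 1 means synergy [published]
    ci_additive_band: float = 0.05   # |CI - 1| <= band reported additive [analysis choice]
    epsilon: float = 0.005       # fa clipping for logit fits [analysis choice]
    n_boot: int = 2000           # bootstrap replicates [analysis choice]
    min_lines: int = 2           # cell lines required for nomination [published]

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError(f"tau must be in (0,1), got {self.tau}")
        if not 0 <= self.delta < 1:
            raise ValueError(f"delta must be in [0,1), got {self.delta}")
        if not 0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon must be in (0,0.5), got {self.epsilon}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be positive")


DEFAULT = Thresholds()

MARKERS = ("b7h3", "psma", "steap1")
MARKER_PAIRS = (("b7h3", "psma"), ("b7h3", "steap1"), ("psma", "steap1"))
PHENOTYPES = ("AR+/NE-", "AR+/NE+", "AR-/NE-", "AR-/NE+")
INTENSITY_CLASSES = ("negative", "weak", "moderate", "strong")
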