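"""Good/bad fiber classification from shape evidence.

Cross-sections that are folded, obliquely cut, clipped by the image
border, or merged with a neighbour produce wrong measurements and must
be excluded before any per-line statistics. This module implements the
rule-based scorer; anything honouring the :func:`score_candidate`
signature (candidate, measures, rules) → verdict can be swapped in,
e.g. a learned classifier, since the pipeline depends only on that
contract.

Default bounds are deliberately generous — roughly ±50% around the
ranges healthy mature fibers occupy — so that the filter rejects
gross defects, not natural variation:

* outer area 20–400 μm² (oblique cuts inflate area by 1/cos(tilt));
* outer circularity 0.30–0.85 (line means sit near 0.51–0.58; folding
  drives circularity down, near-perfect discs suggest debris);
* a lumen must be present, with at most 2 extra (defect) holes;
* border-touching candidates are unmeasurable and rejected;
* θ ≤ 1 up to discretization tolerance (θ above the isoperimetric
  limit means the outline is not a credible single fiber).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import pandas as pd

from .morphometry import ShapeMeasures, theta_of
from .segmentation import FiberCandidate, LabeledScene, measure_candidate

__all__ = [
    "QualityRuleSet",
    "QualityVerdict",
    "score_candidate",
    "filter_scene",
    "THETA_DISCRETIZATION_TOL",
]

#: Slack on the θ ≤ max_theta rule for contour discretization error.
THETA_DISCRETIZATION_TOL = 0.01


@dataclass(frozen=True)
class QualityRuleSet:
    """Bounds defining an acceptable ("good") fiber cross-section."""

    min_area_um2: float = 20.0
    max_area_um2: float = 400.0
    min_outer_circularity: float = 0.30
    max_outer_circularity: float = 0.85
    require_lumen: bool = True
    max_defect_holes: int = 2
    reject_border: bool = True
    max_theta: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        if not self.min_outer_circularity < self.max_outer_circularity:
            raise ValueError("min_outer_circularity must be < max_outer_circularity")
        if self.max_defect_holes < 0 or self.max_theta <= 0:
            raise ValueError("max_defect_holes must be ≥ 0 and max_theta > 0")


@dataclass(frozen=True)
class QualityVerdict:
    """Outcome of scoring one candidate against a rule set."""

    good: bool
    reasons: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if self.good != (len(self.reasons) == 0):
            raise ValueError("good must be true iff no rule failed")


#: Signature any pluggable scorer must honour.
Scorer = Callable[
    [FiberCandidate, tuple[Optional[ShapeMeasures], ShapeMeasures], QualityRuleSet],
    QualityVerdict,
]


def score_candidate(
    candidate: FiberCandidate,
    measures: tuple[Optional[ShapeMeasures], ShapeMeasures],
    rules: QualityRuleSet,
) -> QualityVerdict:
    """Evaluate every rule; deterministic, no hidden state.

    ``score`` is the fraction of applicable rules passed; a rule that
    cannot be evaluated (θ without a lumen) is not counted against the
    candidate beyond the lumen rule itself.
    """
    lumen, outer = measures
    checks: list[tuple[str, bool]] = [
        ("area_min", outer.area >= rules.min_area_um2),
        ("area_max", outer.area <= rules.max_area_um2),
        ("circularity_min", outer.circularity >= rules.min_outer_circularity),
        ("circularity_max", outer.circularity <= rules.max_outer_circularity),
        ("defect_holes", candidate.defect_hole_count <= rules.max_defect_holes),
    ]
    if rules.require_lumen:
        checks.append(("lumen_missing", lumen is not None))
    if rules.reject_border:
        checks.append(("border", not candidate.touches_border))
    if lumen is not None and lumen.area < outer.area:
        theta = theta_of(outer.area - lumen.area, outer.perimeter)
        checks.append(("theta_max", theta <= rules.max_theta + THETA_DISCRETIZATION_TOL))
    elif lumen is not None:
        checks.append(("theta_max", False))  # lumen ≥ fiber: nonsense geometry
    reasons = tuple(name for name, ok in checks if not ok)
    return QualityVerdict(
        good=not reasons, reasons=reasons, score=(len(checks) - len(reasons)) / len(checks)
    )


def filter_scene(
    scene: LabeledScene,
    rules: QualityRuleSet = QualityRuleSet(),
    scorer: Scorer = score_candidate,
) -> tuple[LabeledScene, pd.DataFrame]:
    """Partition a scene into good fibers and a rejection audit table.

    Letters are preserved, never re-assigned, so fiber identities stay
    traceable between the full and filtered scenes. The audit table has
    one row per rejected candidate with the failed-rule identifiers.
    Filtering is idempotent: the good subset passes unchanged.
    """
    good: list[FiberCandidate] = []
    audit_rows = []
    for cand in scene.candidates:
        verdict = scorer(cand, measure_candidate(cand, scene.scale), rules)
        if verdict.good:
            good.append(cand)
        else:
            audit_rows.append(
                {
                    "image_id": scene.image_id,
                    "letter": cand.letter,
                    "score": verdict.score,
                    "reasons": ";".join(verdict.reasons),
                }
            )
    audit = pd.DataFrame(audit_rows, columns=["image_id", "letter", "score", "reasons"])
    return replace(scene, candidates=tuple(good)), audit
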