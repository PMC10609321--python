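"""End-to-end composition: image → good fibers → canonical table."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import table_from_metrics
from .morphometry import CalibrationScale, FiberMetrics, derive_fiber_metrics
from .quality import QualityRuleSet, Scorer, filter_scene, score_candidate
from .segmentation import LabeledScene, measure_candidate, segment_image

__all__ = ["measure_scene", "measure_image"]


def measure_scene(
    scene: LabeledScene,
    rules: QualityRuleSet = QualityRuleSet(),
    line: str = "",
    scorer: Scorer = score_candidate,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quality-filter a segmented scene and tabulate the good fibers.

    Returns (canonical table, rejection audit). Fiber names are
    ``<image_id>_<letter>`` with the letters assigned at segmentation
    time, so rows remain traceable to image positions.
    """
    good, audit = filter_scene(scene, rules, scorer=scorer)
    metrics: list[FiberMetrics] = []
    for cand in good.candidates:
        lumen, outer = measure_candidate(cand, scene.scale)
        if lumen is None:
            continue  # only reachable when require_lumen is off
        metrics.append(
            derive_fiber_metrics(
                lumen, outer, name=f"{scene.image_id}_{cand.letter}", line=line
            )
        )
    return table_from_metrics(metrics), audit


def measure_image(
    image: np.ndarray,
    scale: CalibrationScale,
    image_id: str,
    rules: QualityRuleSet = QualityRuleSet(),
    line: str = "",
    threshold: Optional[float] = None,
    method: str = "otsu",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline on one micrograph: segment, filter, measure."""
    scene = segment_image(image, scale, image_id, method=method, threshold=threshold)
    return measure_scene(scene, rules, line=line)
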