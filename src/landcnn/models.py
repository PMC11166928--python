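"""The twelve candidate landscape models.

Each model is a subset of the four weighted predictors (the empty subset is
the isolation-by-distance null; geographic distance is implicit in every
model).  Habitat shifts and niche suitability never co-occur: both derive
from the same climatic reconstructions and are not independent hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LandscapeModel", "enumerate_models"]


@dataclass(frozen=True)
class LandscapeModel:
    id: int
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if "habitat_shifts" in self.predictors and "niche_suitability" in self.predictors:
            raise ValueError("habitat_shifts and niche_suitability cannot co-occur")

    @property
    def name(self) -> str:
        if not self.predictors:
            return "Geographic distance"
        pretty = {
            "slope": "Slope",
            "rivers": "Rivers",
            "habitat_shifts": "Habitat shifts",
            "niche_suitability": "Environmental niche suitability",
        }
        return " + ".join(pretty[p] for p in self.predictors)

    @property
    def is_dynamic(self) -> bool:
        return any(p in ("habitat_shifts", "niche_suitability") for p in self.predictors)

    @property
    def dynamic_predictor(self) -> str | None:
        for p in ("habitat_shifts", "niche_suitability"):
            if p in self.predictors:
                return p
        return None


def enumerate_models() -> list[LandscapeModel]:
    """The canonical 12-model set, in the standard ordering.

    Models 1-5 are the single-predictor hypotheses (1 = distance-only null),
    6-10 the two-predictor combinations, 11-12 the three-predictor ones;
    every subset of {slope, rivers} is crossed with
    {none, habitat_shifts, niche_suitability}.
    """
    table: list[tuple[str, ...]] = [
        (),
        ("slope",),
        ("rivers",),
        ("habitat_shifts",),
        ("niche_suitability",),
        ("slope", "rivers"),
        ("slope", "habitat_shifts"),
        ("slope", "niche_suitability"),
        ("rivers", "habitat_shifts"),
        ("rivers", "niche_suitability"),
        ("slope", "rivers", "habitat_shifts"),
        ("slope", "rivers", "niche_suitability"),
    ]
    return [LandscapeModel(i + 1, preds) for i, preds in enumerate(table)]
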