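"""End-to-end experiment orchestration.

Wires the pipeline together: enumerate the twelve candidate landscape
models, build labeled training corpora (draw priors -> migration schedule ->
coalescent SNPs -> image), and run the sampling-design sensitivity study
over the four genetic/geographic sampling schemes.

Two ready-made scales are provided.  The full scale is the empirical-mirror
study design (39 demes, 9 sampled with the unbalanced empirical scheme, 4364 SNPs,
2500 examples per model).  The reduced scale — used by the test-suite
experiments so the whole pipeline runs on one CPU in minutes — keeps the
same structure on a smaller problem (12 demes, 6 sampled with 10 sequences
each, 500 SNPs, and a 3-model contrast of distance vs. strong slope vs.
strong rivers with effect weights drawn from the top of the prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classifier import (
    CalibrationReport,
    ClassifierSpec,
    CNNClassifier,
    EvaluationReport,
    REDUCED_SPEC,
    build_classifier,
    calibration_report,
    evaluate_classifier,
    split_dataset,
    train_classifier,
)
from .encoding import SNPImage, encode_image
from .landscape import DemeSet, LayerStack, generate_deme_layout, generate_layer_stack
from .models import LandscapeModel, enumerate_models
from .raster import RasterGrid
from .resistance import build_migration_schedule
from .simulate import (
    EMPIRICAL_MIRROR_SCHEME,
    StudyDesign,
    sample_parameters,
    simulate_genotypes,
)

__all__ = [
    "SamplingScheme",
    "FULL_SCALE_SCHEMES",
    "Landscape",
    "make_landscape",
    "reduced_landscape",
    "reduced_design",
    "selfclass_models",
    "build_training_corpus",
    "relabel_for_training",
    "SchemeResult",
    "run_sampling_experiment",
    "run_selfclass_experiment",
    "SelfClassResult",
]


@dataclass(frozen=True)
class SamplingScheme:
    """A genetic/geographic sampling strategy for the bias study."""

    n_sampled_demes: int
    sequences_per_deme: int

    def __post_init__(self) -> None:
        if self.sequences_per_deme % 2 != 0:
            raise ValueError("sequences_per_deme must be even (2 per individual)")


#: The full-scale four-cell grid: 9 or 39 sampled demes x 2 or 20 sequences.
FULL_SCALE_SCHEMES: tuple[SamplingScheme, ...] = (
    SamplingScheme(9, 2),
    SamplingScheme(9, 20),
    SamplingScheme(39, 2),
    SamplingScheme(39, 20),
)


@dataclass
class Landscape:
    """A fixed landscape: extent, deme layout, and one stack per predictor."""

    extent: RasterGrid
    demes: DemeSet
    stacks: dict[str, LayerStack]


def make_landscape(
    n_rows: int,
    n_cols: int,
    n_demes: int,
    n_sampled: int,
    sample_size_scheme: Sequence[int],
    seed: int,
    layer_params: Mapping[str, Mapping[str, float]] | None = None,
) -> Landscape:
    """Generate the extent, deme layout and all five predictor stacks."""
    layer_params = layer_params or {}
    extent = RasterGrid(values=np.ones((n_rows, n_cols)))
    demes = generate_deme_layout(n_demes, n_sampled, extent, sample_size_scheme, seed)
    ss = np.random.SeedSequence(seed)
    kinds = ("distance", "slope", "rivers", "habitat_shifts", "niche_suitability")
    stacks = {
        kind: generate_layer_stack(
            kind, extent, layer_params.get(kind),
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        for kind, child in zip(kinds, ss.spawn(len(kinds)))
    }
    return Landscape(extent=extent, demes=demes, stacks=stacks)


def full_landscape(seed: int) -> Landscape:
    """The full-scale study layout: 39 demes on a 60x60 grid, 9 sampled with
    the unbalanced empirical scheme (52 individuals).  The grid keeps demes
    several to tens of cells apart, as localities are on a continental-scale
    raster."""
    return make_landscape(60, 60, 39, 9, EMPIRICAL_MIRROR_SCHEME, seed)


def reduced_landscape(seed: int, n_sampled: int = 6, individuals_per_deme: int = 5) -> Landscape:
    """The reduced test-scale layout: 12 demes on a 32x32 grid (roughly the
    full-scale deme density)."""
    return make_landscape(
        32, 32, 12, n_sampled, [individuals_per_deme] * n_sampled, seed
    )


def reduced_design(n_snps: int = 500, strong: bool = True) -> StudyDesign:
    """Reduced study conditions; ``strong`` narrows the effect-weight prior
    to U(4,5) (the top of the full-scale U(2,5) prior) for the clearly
    contrasted 3-model experiment."""
    return StudyDesign(
        n_demes=12,
        n_snps=n_snps,
        weight_range=(4.0, 5.0) if strong else (2.0, 5.0),
    )


def selfclass_models() -> list[LandscapeModel]:
    """The reduced 3-model contrast: distance vs. slope vs. rivers."""
    all_models = enumerate_models()
    return [all_models[0], all_models[1], all_models[2]]


def build_training_corpus(
    design: StudyDesign,
    landscape: Landscape,
    models: Sequence[LandscapeModel],
    n_per_model: int,
    seed: int,
    max_retries: int = 5,
) -> tuple[list[SNPImage], list[dict]]:
    """Simulate and encode a labeled corpus of ``len(models) * n_per_model``
    images over a fixed landscape.

    Every example draws its own parameters from the priors; per-example
    provenance (model id, seed, draw) is returned as a manifest that fully
    determines reproduction.  A failed example is retried with a fresh seed
    up to ``max_retries`` times.
    """
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    images: list[SNPImage] = []
    manifest: list[dict] = []
    ss = np.random.SeedSequence(seed)
    for model in models:
        for k, child in enumerate(ss.spawn(n_per_model)):
            last_err: Exception | None = None
            for attempt, sub in enumerate(child.spawn(max_retries + 1)):
                ex_seed = int(sub.generate_state(1)[0] % (2**31))
                try:
                    rng = np.random.default_rng(ex_seed)
                    draw = sample_parameters(design, model, rng)
                    schedule = build_migration_schedule(
                        model, landscape.stacks, draw.effect_weights,
                        draw.dispersal, landscape.demes,
                        split_gen=design.split_gen,
                    )
                    g = simulate_genotypes(
                        design, landscape.demes, draw, schedule, label=model.id
                    )
                    images.append(encode_image(g))
                    manifest.append(
                        {
                            "model": model.id,
                            "example": k,
                            "seed": ex_seed,
                            "attempt": attempt,
                            "ancestral_ne": draw.ancestral_ne,
                            "dispersal": draw.dispersal,
                            "effect_weights": dict(draw.effect_weights),
                        }
                    )
                    last_err = None
                    break
                except Exception as err:  # retried with a fresh seed
                    last_err = err
            if last_err is not None:
                raise RuntimeError(
                    f"corpus example for model {model.id} failed after "
                    f"{max_retries + 1} attempts"
                ) from last_err
    return images, manifest


def relabel_for_training(images: Sequence[SNPImage]) -> tuple[list[SNPImage], dict[int, int]]:
    """Map model-id labels to contiguous 0-based class labels."""
    ids = sorted({im.label for im in images})
    mapping = {mid: i for i, mid in enumerate(ids)}
    out = [
        SNPImage(im.pixels, im.deme_ids, im.individual_ids, label=mapping[im.label])
        for im in images
    ]
    return out, mapping


@dataclass
class SchemeResult:
    scheme: SamplingScheme
    evaluation: EvaluationReport | None
    calibration: CalibrationReport | None
    flagged: str | None = None      # set when training diverged

    @property
    def accuracy(self) -> float:
        return float("nan") if self.evaluation is None else self.evaluation.overall_accuracy


def _scheme_demes(
    landscape: Landscape, scheme: SamplingScheme, rng: np.random.Generator
) -> DemeSet:
    n_total = len(landscape.demes)
    if scheme.n_sampled_demes > n_total:
        raise ValueError("scheme samples more demes than the layout holds")
    if scheme.n_sampled_demes == n_total:
        ids = [d.id for d in landscape.demes]
    else:
        ids = sorted(
            rng.choice(
                [d.id for d in landscape.demes], size=scheme.n_sampled_demes, replace=False
            ).tolist()
        )
    per = scheme.sequences_per_deme // 2
    return landscape.demes.with_sampling(ids, [per] * len(ids))


def run_sampling_experiment(
    landscape: Landscape,
    schemes: Sequence[SamplingScheme] = FULL_SCALE_SCHEMES,
    models: Sequence[LandscapeModel] | None = None,
    n_train: int = 2000,
    n_test: int = 500,
    n_snps: int = 4364,
    seed: int = 0,
    design: StudyDesign | None = None,
    spec: ClassifierSpec = REDUCED_SPEC,
) -> list[SchemeResult]:
    """Independent corpus + classifier per sampling scheme.

    Each scheme resamples which demes carry genetic data and how many
    sequences each contributes, then runs the full simulate/encode/train/
    evaluate pipeline at the stated budget.  A scheme whose training
    diverges (non-finite loss) is flagged and the others continue.
    """
    if models is None:
        models = enumerate_models()
    base = design or StudyDesign(n_demes=len(landscape.demes), n_snps=n_snps)
    results: list[SchemeResult] = []
    ss = np.random.SeedSequence(seed)
    for scheme, child in zip(schemes, ss.spawn(len(schemes))):
        s1, s2, s3 = [int(c.generate_state(1)[0] % (2**31)) for c in child.spawn(3)]
        demes = _scheme_demes(landscape, scheme, np.random.default_rng(s1))
        scheme_landscape = Landscape(landscape.extent, demes, landscape.stacks)
        dsn = StudyDesign(
            n_demes=base.n_demes, split_gen=base.split_gen,
            ancestral_ne_range=base.ancestral_ne_range,
            deme_size_range=base.deme_size_range, n_snps=n_snps,
            weight_range=base.weight_range, dispersal_range=base.dispersal_range,
        )
        try:
            corpus, _ = build_training_corpus(
                dsn, scheme_landscape, models, n_train + n_test, seed=s2
            )
            corpus, _ = relabel_for_training(corpus)
            train, test = split_dataset(
                corpus, train_fraction=n_train / (n_train + n_test), rng=s3
            )
            clf = build_classifier(train[0].shape, n_models=len(models), spec=spec)
            clf, trace = train_classifier(clf, train, seed=s3)
            if not np.all(np.isfinite(trace)):
                results.append(SchemeResult(scheme, None, None, flagged="non-finite loss"))
                continue
            results.append(
                SchemeResult(
                    scheme,
                    evaluate_classifier(clf, test),
                    calibration_report(clf, test),
                )
            )
        except Exception as err:
            results.append(SchemeResult(scheme, None, None, flagged=str(err)))
    return results


@dataclass
class SelfClassResult:
    evaluation: EvaluationReport
    classifier: CNNClassifier
    train: list[SNPImage]
    test: list[SNPImage]
    train_seed: int


def run_selfclass_experiment(
    seed: int,
    n_train: int = 100,
    n_test: int = 30,
    n_snps: int = 500,
    spec: ClassifierSpec = REDUCED_SPEC,
) -> SelfClassResult:
    """The reduced-scale self-classification experiment: distance vs. strong
    slope vs. strong rivers on the 12-deme layout.

    Returns the evaluation report, the trained classifier and the (0-based
    relabeled) train/test images, so callers can run negative controls on
    the same corpus."""
    ss = np.random.SeedSequence(seed)
    s_land, s_corpus, s_train = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    landscape = reduced_landscape(s_land)
    design = reduced_design(n_snps=n_snps, strong=True)
    corpus, _ = build_training_corpus(
        design, landscape, selfclass_models(), n_train + n_test, seed=s_corpus
    )
    corpus, _ = relabel_for_training(corpus)
    train, test = split_dataset(
        corpus, train_fraction=n_train / (n_train + n_test), rng=s_train
    )
    clf = build_classifier(train[0].shape, n_models=3, spec=spec)
    clf, _ = train_classifier(clf, train, seed=s_train)
    return SelfClassResult(
        evaluation=evaluate_classifier(clf, test), classifier=clf,
        train=train, test=test, train_seed=s_train,
    )
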