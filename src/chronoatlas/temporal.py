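"""Temporal atlas propagation across a developmental gap.

A labeled adult-end atlas is carried to a target (e.g. neonatal) space
through a ladder of age-ordered intermediate templates: each template is
registered to its older neighbour, the oldest to the atlas, and the target
to the youngest.  The resulting pull-back transforms are concatenated and
labels are transported through the composed chain in a single
nearest-neighbour pass, avoiding cumulative interpolation erosion.

Inter-template and template-to-atlas links use NMI (contrast changes with
myelination), while the intra-modality target-side link uses NCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import ImageVolume, LabelMap
from .metrics import ncc_metric
from .registration import RegistrationConfig, affine_register, diffeo_register
from .resample import resample_intensity, resample_labels
from .transforms import TransformChain, concat_chain

__all__ = [
    "TemporalSequence",
    "ChainLinkReport",
    "build_temporal_chain",
    "propagate_atlas_labels",
    "evaluate_chain_cc",
]


@dataclass
class TemporalSequence:
    """Ordered age templates, oldest (labeled end) first, ages strictly
    decreasing.  ``metric_schedule`` optionally overrides the per-step metric
    (length = number of inter-template steps)."""

    templates: list[ImageVolume]
    ages: list[float]
    metric_schedule: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.templates) < 1:
            raise ValueError("a temporal sequence needs at least 1 template")
        if len(self.ages) != len(self.templates):
            raise ValueError("one age per template required")
        if not all(a > b for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError(f"ages must be strictly decreasing, got {self.ages}")
        if self.metric_schedule is not None and len(self.metric_schedule) != len(
            self.templates
        ) - 1:
            raise ValueError("metric_schedule must have one entry per step")

    def __len__(self) -> int:
        return len(self.templates)

    def space_name(self, i: int) -> str:
        return f"stage{i}"


@dataclass
class ChainLinkReport:
    """Per-link diagnostics recorded while building a chain."""

    target: str
    source: str
    metric: str
    ncc_after: float
    converged: bool


def _register_link(
    fixed: ImageVolume,
    moving: ImageVolume,
    metric: str,
    config: RegistrationConfig,
    target: str,
    source: str,
):
    cfg = RegistrationConfig(
        levels=config.levels,
        max_iters_per_level=config.max_iters_per_level,
        metric=metric,
        histogram_bins=config.histogram_bins,
        update_smoothing_sigma=config.update_smoothing_sigma,
        field_smoothing_sigma=config.field_smoothing_sigma,
        step_size=config.step_size,
        convergence_tol=config.convergence_tol,
    )
    aff = affine_register(fixed, moving, metric=metric, config=cfg)
    res = diffeo_register(fixed, moving, config=cfg, init=aff)
    res.forward.target = target
    res.forward.source = source
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cc = ncc_metric(fixed, res.warped_moving)
    report = ChainLinkReport(target, source, metric, cc, res.converged)
    return res.forward, report


def build_temporal_chain(
    atlas_image: ImageVolume | None,
    seq: TemporalSequence,
    target: ImageVolume | None,
    config: RegistrationConfig | None = None,
) -> TransformChain:
    """Build the composed pull-back chain target -> ... -> atlas.

    The chain's links, first to last: target->youngest template (NCC,
    intra-modality), youngest->next older, ..., second-oldest->oldest (NMI),
    oldest->atlas (NMI).  ``atlas_image`` and ``target`` may each be None to
    chain a bare template ladder.  Non-converged links are kept but flagged
    in the chain's ``reports`` (attached attribute), with a warning naming
    the link.
    """
    config = config or RegistrationConfig()
    links = []
    reports: list[ChainLinkReport] = []
    n = len(seq)
    if n < 2 and target is None and atlas_image is None:
        raise ValueError("chaining a bare ladder needs at least 2 templates")

    if target is not None:
        fwd, rep = _register_link(
            target, seq.templates[-1], "ncc", config, "target", seq.space_name(n - 1)
        )
        links.append(fwd)
        reports.append(rep)

    # youngest -> oldest, one rung at a time
    for i in range(n - 1, 0, -1):
        metric = (
            seq.metric_schedule[i - 1] if seq.metric_schedule is not None else "nmi"
        )
        fwd, rep = _register_link(
            seq.templates[i],
            seq.templates[i - 1],
            metric,
            config,
            seq.space_name(i),
            seq.space_name(i - 1),
        )
        links.append(fwd)
        reports.append(rep)

    if atlas_image is not None:
        fwd, rep = _register_link(
            seq.templates[0], atlas_image, "nmi", config, seq.space_name(0), "atlas"
        )
        links.append(fwd)
        reports.append(rep)

    for rep in reports:
        if not rep.converged:
            warnings.warn(
                f"chain link {rep.target} -> {rep.source} did not converge",
                stacklevel=2,
            )
    chain = concat_chain(links)
    chain.reports = reports  # type: ignore[attr-defined]
    return chain


def propagate_atlas_labels(
    atlas_labels: LabelMap, chain: TransformChain, target_grid
) -> LabelMap:
    """Transport atlas labels through the composed chain onto the target grid.

    Nearest-neighbour sampling happens exactly once, through the full
    composition, so no intermediate quantization accumulates and no label ID
    outside the atlas's set can appear.
    """
    if chain.links and chain.links[-1].source and chain.links[-1].source != "atlas":
        raise ValueError(
            f"chain must end in atlas space, ends in {chain.links[-1].source!r}"
        )
    return resample_labels(atlas_labels, chain, target_grid)


def evaluate_chain_cc(
    seq: TemporalSequence, chain: TransformChain
) -> dict[str, object]:
    """Per-step NCC between each warped source template and its target.

    Only links joining two sequence stages are evaluated (a chain may also
    carry target- and atlas-side links).  Returns per-step values plus their
    mean and SD — the consecutive-time-point registration quality summary.
    """
    stage_names = {seq.space_name(i): i for i in range(len(seq))}
    per_step: list[float] = []
    steps: list[tuple[str, str]] = []
    for link in chain.links:
        if link.target in stage_names and link.source in stage_names:
            fixed = seq.templates[stage_names[link.target]]
            moving = seq.templates[stage_names[link.source]]
            warped = resample_intensity(moving, link, fixed.grid)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_step.append(ncc_metric(fixed, warped))
            steps.append((link.target, link.source))
    per_step_arr = np.asarray(per_step)
    return {
        "steps": steps,
        "ncc": per_step,
        "mean": float(per_step_arr.mean()) if per_step else float("nan"),
        "sd": float(per_step_arr.std(ddof=1)) if len(per_step) > 1 else 0.0,
    }
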