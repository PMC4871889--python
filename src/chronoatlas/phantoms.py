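"""Seeded synthetic phantoms: labeled head phantoms, deformed cohorts and
aging template sequences.

The base phantom is a concentric "head": background, a CSF rim, a cortical
gray-matter ribbon and a white-matter core, with four pairs of lateral deep
structures, one unpaired midline structure, five named landmarks at
structure extrema, and a low-amplitude smooth texture inside the head so
homogeneous regions still carry registration information.  Cohort subjects
are generated by exponentiating random smoothed velocity fields (so every
true warp is diffeomorphic with an exact inverse), plus a smooth
multiplicative bias field and Gaussian noise.  Aging sequences shrink the
head stage by stage while the white/gray intensity contrast crosses from
adult-like (WM bright) to neonatal (WM dark).

All randomness derives from integer seeds; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from warnings import warn

import numpy as np
from scipy import ndimage

from .grids import ImageVolume, LabelMap, LabelScheme, LandmarkSet, SchemeEntry
from .resample import resample_intensity, resample_labels
from .transforms import (
    AffineTransform,
    CompositeTransform,
    DisplacementField,
    TransformChain,
    scaling_and_squaring,
)
from .temporal import TemporalSequence

__all__ = [
    "SyntheticCohortSpec",
    "AgingSequenceSpec",
    "CohortSubject",
    "make_phantom",
    "make_cohort",
    "make_aging_sequence",
    "phantom_scheme",
    "random_diffeomorphism",
]

# label IDs of the bundled mini scheme; the left-right axis is axis 0 and
# "left" is the higher-index side
CSF, GM, WM = 1, 2, 3
BLOB_IDS = {
    "thalamus": (10, 11),
    "putamen": (12, 13),
    "caudate": (14, 15),
    "hippocampus": (16, 17),
}
MIDLINE = 20

ADULT_INTENSITIES = {
    "bg": 0.0,
    "csf": 0.22,
    "gm": 0.5,
    "wm": 0.85,
    "thalamus": 0.65,
    "putamen": 0.32,
    "caudate": 0.72,
    "hippocampus": 0.42,
    "midline": 0.58,
}


def phantom_scheme() -> LabelScheme:
    """The bundled mini label scheme for the phantom parcellation."""
    entries: dict[int, SchemeEntry] = {
        CSF: SchemeEntry("csf", "none"),
        GM: SchemeEntry("gm", "none"),
        WM: SchemeEntry("wm", "none"),
        MIDLINE: SchemeEntry("midline body", "none", None, "central"),
    }
    lobes = {
        "thalamus": "anterior",
        "putamen": "anterior",
        "caudate": "posterior",
        "hippocampus": "posterior",
    }
    for name, (lid, rid) in BLOB_IDS.items():
        entries[lid] = SchemeEntry(f"{name} left", "left", rid, lobes[name])
        entries[rid] = SchemeEntry(f"{name} right", "right", lid, lobes[name])
    return LabelScheme(entries)


# blob placement as fractions of grid size: (offset along LR axis,
# offsets along remaining axes, radius)
_BLOB_GEOMETRY = {
    "thalamus": (0.17, -0.04, 0.048),
    "putamen": (0.11, 0.15, 0.042),
    "caudate": (0.23, 0.11, 0.038),
    "hippocampus": (0.09, -0.18, 0.042),
}


def make_phantom(
    size: int = 128,
    laterality: float | dict[str, float] | None = None,
    seed: int = 0,
    rank: int = 2,
    spacing: float = 1.0,
    intensities: dict[str, float] | None = None,
    scale: float = 1.0,
) -> tuple[ImageVolume, LabelMap, LandmarkSet]:
    """Build the labeled base phantom.

    ``laterality`` is a V_L/V_R target volume ratio, either one factor for
    every pair or a mapping of pair base name -> factor; the left blob's
    radius is scaled by ``factor**(1/rank)``.  ``scale`` shrinks all
    structure radii (used by the aging sequence).  ``intensities`` overrides
    the adult-contrast tissue values.
    """
    if size < 48:
        raise ValueError(f"size must be >= 48 to fit the structures, got {size}")
    if rank not in (2, 3):
        raise ValueError("rank must be 2 or 3")
    vals = dict(ADULT_INTENSITIES)
    if intensities:
        vals.update(intensities)
    if laterality is None:
        lat = {name: 1.0 for name in BLOB_IDS}
    elif np.isscalar(laterality):
        lat = {name: float(laterality) for name in BLOB_IDS}
    else:
        lat = {name: float(laterality.get(name, 1.0)) for name in BLOB_IDS}

    shape = (size,) * rank
    c = (size - 1) / 2.0
    axes = [np.arange(size, dtype=float) - c for _ in range(rank)]
    mesh = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(sum(m**2 for m in mesh))

    R_head = 0.42 * size * scale
    t_csf = 0.055 * size * scale
    t_gm = 0.10 * size * scale

    labels = np.zeros(shape, dtype=np.int32)
    labels[r <= R_head] = CSF
    labels[r <= R_head - t_csf] = GM
    labels[r <= R_head - t_csf - t_gm] = WM

    img = np.zeros(shape)
    img[labels == CSF] = vals["csf"]
    img[labels == GM] = vals["gm"]
    img[labels == WM] = vals["wm"]

    def _blob_mask(center: np.ndarray, radius: float) -> np.ndarray:
        d = np.sqrt(sum((m - cc) ** 2 for m, cc in zip(mesh, center)))
        return d <= radius

    for name, (lid, rid) in BLOB_IDS.items():
        dx, dy, frac_r = _BLOB_GEOMETRY[name]
        radius = frac_r * size * scale
        off = np.zeros(rank)
        off[0] = dx * size * scale
        off[1] = dy * size * scale
        # left = higher index along axis 0
        left_r = radius * lat[name] ** (1.0 / rank)
        for center, this_id, this_r in (
            (off, lid, left_r),
            (off * np.array([-1] + [1] * (rank - 1)), rid, radius),
        ):
            m = _blob_mask(center, this_r)
            labels[m] = this_id
            img[m] = vals[name]

    # unpaired midline structure: an elongated ellipse on the LR midplane
    mid_r = np.sqrt(
        (mesh[0] / (0.035 * size * scale)) ** 2
        + sum((m / (0.10 * size * scale)) ** 2 for m in mesh[1:])
    )
    mid_mask = mid_r <= 1.0
    labels[mid_mask] = MIDLINE
    img[mid_mask] = vals["midline"]

    # smooth seeded texture inside the head so flat tissue still guides
    # registration; mirror-symmetrized so laterality 1 keeps exact symmetry,
    # and sampled in anatomy coordinates so it scales with the structures
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), 0.03 * size)
    tex = 0.5 * (tex + np.flip(tex, axis=0))
    ptp = tex.max() - tex.min()
    if ptp > 0:
        tex = 0.05 * (tex - tex.mean()) / ptp
    if scale != 1.0:
        coords = [m / scale + c for m in mesh]
        tex = ndimage.map_coordinates(tex, coords, order=1, mode="nearest")
    img = np.where(labels > 0, img + tex, img)
    img = ndimage.gaussian_filter(img, 0.8)

    landmarks = {}
    sp = float(spacing)
    landmarks["left_lateral"] = np.array([c + R_head] + [c] * (rank - 1)) * sp
    landmarks["right_lateral"] = np.array([c - R_head] + [c] * (rank - 1)) * sp
    ant = np.full(rank, c)
    ant[1] = c + R_head
    post = np.full(rank, c)
    post[1] = c - R_head
    landmarks["anterior_pole"] = ant * sp
    landmarks["posterior_pole"] = post * sp
    landmarks["midline_center"] = np.full(rank, c) * sp

    image = ImageVolume(img, (sp,) * rank)
    label_map = LabelMap(labels, (sp,) * rank)
    return image, label_map, LandmarkSet(landmarks)


def random_diffeomorphism(
    shape: tuple[int, ...],
    amplitude: float,
    smoothness: float,
    rng: np.random.Generator,
    spacing: float = 1.0,
) -> tuple[DisplacementField, DisplacementField]:
    """Random diffeomorphic warp and its exact inverse.

    A white-noise velocity field is Gaussian-smoothed (``smoothness``
    voxels), scaled so its maximum norm is ``amplitude`` voxels, and
    exponentiated by scaling-and-squaring; the inverse is the exponential of
    the negated velocity.  If the forward Jacobian is not everywhere
    positive the amplitude is reduced (flagged with a warning) — in practice
    the exponential construction keeps it positive.
    """
    rank = len(shape)
    v = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), smoothness) for _ in range(rank)],
        axis=-1,
    )
    norms = np.linalg.norm(v, axis=-1)
    if norms.max() > 0:
        v *= amplitude / norms.max()
    v *= spacing  # voxel amplitude -> mm
    for _ in range(5):
        fwd = scaling_and_squaring(DisplacementField(v, (spacing,) * rank))
        from .transforms import jacobian_determinant

        interior = tuple(slice(1, -1) for _ in range(rank))
        if jacobian_determinant(fwd).data[interior].min() > 0:
            break
        warn("requested warp amplitude produced folding; reduced by 20%", stacklevel=2)
        v *= 0.8
    inv = scaling_and_squaring(DisplacementField(-v, (spacing,) * rank))
    return fwd, inv


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate a small neonatal-scale study at desk scale: 8 subjects
    on a 128-voxel grid, smooth anatomical variability of ~3 voxels, 2%
    intensity noise and a 10% smooth bias field, volumetrically symmetric
    anatomy (laterality 1).
    """

    n_subjects: int = 8
    size: int = 128
    amplitude: float = 3.0
    smoothness: float = 4.0
    noise_sd: float = 0.02
    bias_amplitude: float = 0.1
    laterality: float | dict[str, float] = 1.0
    seed: int = 0
    rank: int = 2
    spacing: float = 1.0
    intensities: dict | None = None  # tissue value overrides (e.g. neonatal WM)
    scale: float = 1.0  # overall anatomy scale relative to the base phantom

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class CohortSubject:
    """One synthetic subject with every ground truth retained."""

    image: ImageVolume
    labels: LabelMap
    true_transform: CompositeTransform  # subject coords -> phantom coords
    true_inverse: CompositeTransform  # phantom coords -> subject coords
    landmarks: LandmarkSet  # true positions in subject space


def make_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[tuple[ImageVolume, LabelMap, LandmarkSet], list[CohortSubject]]:
    """Generate the base phantom and a cohort of deformed subjects.

    Returns ``(phantom, subjects)`` where ``phantom`` is the
    (image, labels, landmarks) triple and each subject retains its true
    warp, inverse warp and landmark positions for recovery tests.
    """
    phantom = make_phantom(
        size=spec.size,
        laterality=spec.laterality,
        seed=spec.seed,
        rank=spec.rank,
        spacing=spec.spacing,
        intensities=spec.intensities,
        scale=spec.scale,
    )
    base_img, base_labels, base_lm = phantom
    shape = base_img.shape
    subjects: list[CohortSubject] = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng([spec.seed, i])
        if spec.amplitude > 0:
            fwd, inv = random_diffeomorphism(
                shape, spec.amplitude, spec.smoothness, rng, spec.spacing
            )
        else:
            from .grids import Grid

            g = Grid(shape, (spec.spacing,) * spec.rank, (0.0,) * spec.rank)
            fwd = DisplacementField.zeros(g)
            inv = DisplacementField.zeros(g)
        T_fwd = CompositeTransform.from_displacement(
            fwd, target=f"subject{i}", source="phantom"
        )
        T_inv = CompositeTransform.from_displacement(
            inv, target="phantom", source=f"subject{i}"
        )
        img = resample_intensity(base_img, T_fwd, base_img.grid)
        labels = resample_labels(base_labels, T_fwd, base_labels.grid)

        data = img.data
        if spec.bias_amplitude > 0:
            bias = ndimage.gaussian_filter(
                rng.standard_normal(shape), 0.25 * spec.size
            )
            ptp = bias.max() - bias.min()
            if ptp > 0:
                bias = 1.0 + spec.bias_amplitude * 2 * (bias - bias.mean()) / ptp
            else:
                bias = np.ones(shape)
            data = data * bias
        if spec.noise_sd > 0:
            rng_range = base_img.data.max() - base_img.data.min()
            data = data + rng.normal(0, spec.noise_sd * rng_range, shape)
        img = ImageVolume(data, img.spacing, img.origin)

        lm = LandmarkSet(
            {name: p + inv.sample(p) for name, p in base_lm.points.items()}
        )
        subjects.append(CohortSubject(img, labels, T_fwd, T_inv, lm))
    return phantom, subjects


@dataclass
class AgingSequenceSpec:
    """Study conditions for a synthetic aging template ladder.

    The oldest stage is full size with adult contrast (WM brighter than
    GM); toward the youngest stage the head shrinks (default scales 1.0 ->
    0.8) and the WM intensity slides below GM, crossing exactly once —
    the neonatal contrast inversion.
    """

    n_stages: int = 6
    size: int = 128
    scales: list[float] | None = None
    wm_intensities: list[float] | None = None
    gm_intensity: float = 0.5
    deformation_amplitude: float = 1.0
    smoothness: float = 4.0
    noise_sd: float = 0.01
    seed: int = 0
    rank: int = 2
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.scales is None:
            if self.n_stages == 1:
                self.scales = [1.0]
            else:
                self.scales = list(np.linspace(1.0, 0.8, self.n_stages))
        if self.wm_intensities is None:
            if self.n_stages == 1:
                self.wm_intensities = [0.85]
            else:
                self.wm_intensities = list(np.linspace(0.85, 0.35, self.n_stages))
        if len(self.scales) != self.n_stages or len(self.wm_intensities) != self.n_stages:
            raise ValueError("per-stage schedules must have n_stages entries")
        if not all(a >= b for a, b in zip(self.scales, self.scales[1:])):
            raise ValueError("scales must be monotone non-increasing")
        diffs = np.diff(self.wm_intensities)
        if not (np.all(diffs <= 0) or np.all(diffs >= 0)):
            raise ValueError("wm intensity schedule must be monotone")


def make_aging_sequence(
    spec: AgingSequenceSpec,
) -> tuple[TemporalSequence, list[TransformChain]]:
    """Generate the age-template ladder and the true stage-to-stage warps.

    Returns ``(sequence, true_transforms)``; ``true_transforms[k]`` maps
    stage k+1 (younger) coordinates to stage k (older) coordinates, as a
    chain (younger stage's warp, the inter-stage scaling about the grid
    centre, the older stage's inverse warp).  With a single stage the truth
    list is empty.
    """
    templates: list[ImageVolume] = []
    warps: list[tuple[DisplacementField, DisplacementField] | None] = []
    shape = (spec.size,) * spec.rank
    c_mm = (spec.size - 1) / 2.0 * spec.spacing

    for k in range(spec.n_stages):
        img, _, _ = make_phantom(
            size=spec.size,
            seed=spec.seed,
            rank=spec.rank,
            spacing=spec.spacing,
            intensities={"wm": float(spec.wm_intensities[k])},
            scale=float(spec.scales[k]),
        )
        rng = np.random.default_rng([spec.seed, 1000 + k])
        if spec.deformation_amplitude > 0 and k > 0:
            fwd, inv = random_diffeomorphism(
                shape, spec.deformation_amplitude, spec.smoothness, rng, spec.spacing
            )
            warped = resample_intensity(
                img, CompositeTransform.from_displacement(fwd), img.grid
            )
            warps.append((fwd, inv))
        else:
            warped = img
            warps.append(None)
        data = warped.data
        if spec.noise_sd > 0:
            data = data + rng.normal(0, spec.noise_sd, shape)
        templates.append(ImageVolume(data, img.spacing, img.origin))

    ages = list(np.linspace(4.5, 0.0, spec.n_stages)) if spec.n_stages > 1 else [0.0]
    seq = TemporalSequence(templates=templates, ages=ages)

    truths: list[TransformChain] = []
    rank = spec.rank
    for k in range(spec.n_stages - 1):
        links = []
        younger = warps[k + 1]
        if younger is not None:
            links.append(
                CompositeTransform.from_displacement(
                    younger[0], target=f"stage{k + 1}", source=f"base{k + 1}"
                )
            )
        ratio = spec.scales[k] / spec.scales[k + 1]
        A = AffineTransform(
            np.eye(rank) * ratio, np.full(rank, c_mm * (1 - ratio))
        )
        links.append(
            CompositeTransform(A, None, target=f"base{k + 1}", source=f"base{k}")
        )
        older = warps[k]
        if older is not None:
            links.append(
                CompositeTransform.from_displacement(
                    older[1], target=f"base{k}", source=f"stage{k}"
                )
            )
        truths.append(TransformChain(links))
    return seq, truths
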