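"""Synthetic rodent-EPI phantoms with surface-coil bias.

Real single-loop surface-coil EPI shows a strong multiplicative intensity
falloff with distance from the coil, a scalp/muscle shell around the brain
(much brighter in spin-echo than gradient-echo contrast), and — for the
spin-echo rat protocol — an external reference object above the head.  This
module builds labeled head phantoms with those features and produces
training pairs:

* ``source``  — full head, multiplied by the coil sensitivity field, plus
  additive Gaussian noise (analyses operate on real-valued magnitude data,
  so the noise model is Gaussian, keeping the noiseless limit exact);
* ``target``  — the bias-free intensities restricted to the brain mask
  (zero elsewhere), i.e. the ideal inhomogeneity-corrected and
  brain-extracted image;
* ``brain_mask`` — the ground-truth brain voxels.

The coil sensitivity uses the on-axis field magnitude of a circular loop,
``s(d) = a^2 / (a^2 + d^2)^{3/2}`` normalized to 1 at the coil center, with
a configurable sensitivity floor:  ``b = floor + (1 - floor) * s_norm``.

Every operation is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import Volume, write_volume, read_volume, write_sidecar, read_sidecar

__all__ = [
    "GE",
    "SE",
    "LABELS",
    "PhantomSpec",
    "CoilProfile",
    "LabeledVolume",
    "ImagePair",
    "Dataset",
    "default_spec",
    "default_profile",
    "make_brain_phantom",
    "make_coil_bias",
    "make_pair",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]

GE = "GE"
SE = "SE"

#: Integer label code of the phantom compartments.
LABELS = {
    "background": 0,
    "WM": 1,
    "GM": 2,
    "CSF": 3,
    "shell": 4,
    "external_phantom": 5,
}


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic head.

    Geometry is in voxel units; intensities are relative (arbitrary) units.
    ``brain_center`` defaults to mid-plane in x/y and slightly ventral in z
    so that the dorsal coil side has room for the shell and, for SE, the
    external reference object.
    """

    grid_shape: tuple = (64, 64, 16)
    voxel_size: tuple = (0.3, 0.3, 0.5)
    modality: str = GE
    brain_axes: tuple = None          # ellipsoid semi-axes, voxels
    brain_center: tuple = None        # voxels
    shell_thickness: float = None     # voxels
    shell_intensity: float = None     # relative units
    tissue_intensities: dict = None   # {"WM","GM","CSF"} -> relative units
    external_phantom: bool = False
    phantom_center: tuple = None      # voxels; derived when None
    phantom_radius: float = None      # voxels
    phantom_intensity: float = 1.2
    texture_amp: float = 0.05         # within-tissue intensity texture
    smooth_sigma: float = 0.6         # voxels, edge softening
    noise_sigma: float = 0.05         # relative units, source only
    seed: int = 0

    def __post_init__(self):
        nx, ny, nz = self.grid_shape
        if self.modality not in (GE, SE):
            raise ValueError(f"modality must be {GE!r} or {SE!r}")
        if self.brain_axes is None:
            # the SE protocol images the larger rat brain, which fills more
            # of the field of view than the GE (mouse) protocol
            if self.modality == SE:
                self.brain_axes = (0.36 * nx, 0.33 * ny, 0.28 * nz)
            else:
                self.brain_axes = (0.30 * nx, 0.27 * ny, 0.25 * nz)
        if self.brain_center is None:
            z_frac = 0.40 if self.modality == SE else 0.42
            self.brain_center = (0.5 * nx, 0.5 * ny, z_frac * nz)
        if self.shell_thickness is None:
            self.shell_thickness = max(1.0, round(0.08 * nz))
        if self.shell_intensity is None:
            # scalp/muscle is much brighter in spin-echo contrast
            self.shell_intensity = 0.9 if self.modality == SE else 0.35
        if self.tissue_intensities is None:
            # T2*-weighted (GE) versus T2-weighted (SE) tissue contrast:
            # CSF is far brighter and WM/GM contrast stronger at the SE
            # protocol's long echo time
            if self.modality == SE:
                self.tissue_intensities = {"WM": 0.55, "GM": 0.95,
                                           "CSF": 1.8}
            else:
                self.tissue_intensities = {"WM": 0.7, "GM": 1.0, "CSF": 1.4}
        self.validate()

    def validate(self):
        nx, ny, nz = self.grid_shape
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 4 voxels")
        if any(a <= 0 for a in self.brain_axes):
            raise ValueError("brain semi-axes must be positive")
        for c, a, n, name in zip(self.brain_center, self.brain_axes,
                                 self.grid_shape, "xyz"):
            if c - a - self.shell_thickness < 0 or \
               c + a + self.shell_thickness > n:
                raise ValueError(
                    f"brain plus shell exceeds the grid along {name}: "
                    f"center {c:.1f}, semi-axis {a:.1f}, "
                    f"shell {self.shell_thickness}, grid {n}"
                )
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        if any(v < 0 for v in self.tissue_intensities.values()) or \
           self.shell_intensity < 0 or self.phantom_intensity < 0:
            raise ValueError("intensities must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.external_phantom and self.modality != SE:
            raise ValueError("the external reference phantom is SE-only")
        if self.external_phantom:
            ctr, r = self._phantom_geometry()
            for c, n in zip(ctr, self.grid_shape):
                if c - r < 0 or c + r > n:
                    raise ValueError("external phantom exceeds the grid")

    def _phantom_geometry(self):
        """Sphere above the head (dorsal side, toward the coil)."""
        nx, ny, nz = self.grid_shape
        top = self.brain_center[2] + self.brain_axes[2] + self.shell_thickness
        if self.phantom_radius is None:
            r = min(0.07 * nz, max(0.5, (nz - top) / 2.0 - 0.6))
        else:
            r = self.phantom_radius
        if self.phantom_center is None:
            ctr = (0.5 * nx, 0.5 * ny, (top + nz) / 2.0)
        else:
            ctr = self.phantom_center
        return ctr, r

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class CoilProfile:
    """Single-loop receive coil placed above (dorsal to) the head.

    ``coil_center`` is in voxel coordinates (it normally sits outside the
    grid along +z), ``coil_radius`` in mm, and ``floor`` is the minimum
    relative sensitivity retained far from the coil.
    """

    coil_center: tuple
    coil_radius: float
    floor: float = 0.15

    def __post_init__(self):
        if not 0 < self.floor <= 1:
            raise ValueError("floor must lie in (0, 1]")
        if self.coil_radius <= 0:
            raise ValueError("coil_radius must be positive")

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class LabeledVolume:
    """Bias-free phantom: intensities, compartment labels, brain mask."""

    intensity: np.ndarray
    labels: np.ndarray
    brain_mask: np.ndarray


@dataclass
class ImagePair:
    """One training/testing unit: biased source and clean extracted target."""

    source: np.ndarray
    target: np.ndarray
    brain_mask: np.ndarray
    modality: str
    spec: PhantomSpec = None
    profile: CoilProfile = None

    @property
    def grid_shape(self):
        return self.source.shape


@dataclass
class Dataset:
    """Ordered pairs with a train/test split and composition counts."""

    pairs: list
    split: list
    composition: dict = field(default_factory=dict)

    @property
    def train_pairs(self):
        return [p for p, s in zip(self.pairs, self.split) if s == "train"]

    @property
    def test_pairs(self):
        return [p for p, s in zip(self.pairs, self.split) if s == "test"]


def default_spec(modality: str = GE, grid_shape=(64, 64, 16),
                 voxel_size=(0.3, 0.3, 0.5), seed: int = 0,
                 **overrides) -> PhantomSpec:
    """A spec with geometry scaled to the grid; SE enables the external
    reference object by default."""
    kw = dict(grid_shape=tuple(grid_shape), voxel_size=tuple(voxel_size),
              modality=modality, seed=seed)
    if modality == SE:
        kw["external_phantom"] = True
    kw.update(overrides)
    return PhantomSpec(**kw)


def default_profile(grid_shape=(64, 64, 16), voxel_size=(0.3, 0.3, 0.5),
                    floor: float = 0.15) -> CoilProfile:
    """Loop coil centered over the head, just above the dorsal grid face."""
    nx, ny, nz = grid_shape
    center = (0.5 * nx, 0.5 * ny, 1.15 * nz)
    radius = 0.35 * nx * voxel_size[0]  # mm, scales with the field of view
    return CoilProfile(coil_center=center, coil_radius=radius, floor=floor)


def _ellipsoid(grid_shape, center, axes):
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) + 0.5
                           for n in grid_shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(coords, center, axes))
    return q <= 1.0


def make_brain_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Build the labeled, bias-free head phantom for one spec.

    The brain is an ellipsoid with a WM core, a GM rim and two small CSF
    pockets at fixed fractional positions; a scalp/muscle shell of the
    requested thickness surrounds it, and SE specs may add a disjoint
    high-intensity sphere above the head.  A smooth seeded texture gives
    the tissue interior realistic local structure.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    ctr = spec.brain_center
    axes = spec.brain_axes
    labels = np.zeros(shape, dtype=np.int16)

    brain = _ellipsoid(shape, ctr, axes)
    labels[brain] = LABELS["GM"]
    wm = _ellipsoid(shape, ctr, tuple(0.55 * a for a in axes))
    labels[wm] = LABELS["WM"]
    # two CSF pockets at fixed fractional offsets inside the brain
    for sx in (-1.0, 1.0):
        pocket = _ellipsoid(
            shape,
            (ctr[0] + sx * 0.35 * axes[0], ctr[1], ctr[2] + 0.25 * axes[2]),
            tuple(max(0.5, 0.15 * a) for a in axes),
        )
        labels[pocket & brain] = LABELS["CSF"]

    if spec.shell_thickness > 0:
        dist = ndimage.distance_transform_edt(~brain)
        shell = (~brain) & (dist <= spec.shell_thickness)
        labels[shell] = LABELS["shell"]

    if spec.external_phantom:
        pctr, pr = spec._phantom_geometry()
        sphere = _ellipsoid(shape, pctr, (pr, pr, pr))
        if np.any(sphere & (labels > 0)):
            raise ValueError("external phantom overlaps the head")
        labels[sphere] = LABELS["external_phantom"]

    lut = np.zeros(6, dtype=np.float64)
    lut[LABELS["WM"]] = spec.tissue_intensities["WM"]
    lut[LABELS["GM"]] = spec.tissue_intensities["GM"]
    lut[LABELS["CSF"]] = spec.tissue_intensities["CSF"]
    lut[LABELS["shell"]] = spec.shell_intensity
    lut[LABELS["external_phantom"]] = spec.phantom_intensity
    intensity = lut[labels]

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.texture_amp > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal(shape), 1.0)
        intensity = intensity * (1.0 + spec.texture_amp * texture)
    if spec.smooth_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.smooth_sigma)
    # confine support to the labeled compartments so the brain mask stays
    # exactly the nonzero support when no shell/phantom is present
    intensity = np.clip(intensity, 0.0, None) * (labels > 0)

    brain_mask = (labels >= LABELS["WM"]) & (labels <= LABELS["CSF"])
    return LabeledVolume(intensity=intensity.astype(np.float32),
                         labels=labels, brain_mask=brain_mask)


def make_coil_bias(profile: CoilProfile, grid_shape,
                   voxel_size=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Multiplicative coil sensitivity field in [floor, 1].

    ``b(r) = floor + (1 - floor) * s(d)`` with the on-axis loop falloff
    ``s(d) = a^3 / (a^2 + d^2)^{3/2}`` (1 at d = 0), where d is the mm
    distance from the coil center.
    """
    coords = np.meshgrid(*[(np.arange(n, dtype=np.float64) + 0.5) * v
                           for n, v in zip(grid_shape, voxel_size)],
                         indexing="ij")
    cc = [c * v for c, v in zip(profile.coil_center, voxel_size)]
    d2 = sum((g - c) ** 2 for g, c in zip(coords, cc))
    a = profile.coil_radius
    s = a ** 3 / (a ** 2 + d2) ** 1.5
    return (profile.floor + (1.0 - profile.floor) * s).astype(np.float32)


def make_pair(spec: PhantomSpec, profile: CoilProfile | None = None) -> ImagePair:
    """Generate one (source, target, mask) pair.

    source = intensity x bias + N(0, noise_sigma), clipped at 0;
    target = bias-free intensity restricted to the brain mask, noise-free.
    """
    if profile is None:
        profile = default_profile(spec.grid_shape, spec.voxel_size)
    lv = make_brain_phantom(spec)
    bias = make_coil_bias(profile, spec.grid_shape, spec.voxel_size)
    source = lv.intensity.astype(np.float64) * bias
    if spec.noise_sigma > 0:
        # the noise stream is split from the texture stream of the same seed
        noise_rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed).spawn(2)[1])
        source = source + spec.noise_sigma * noise_rng.standard_normal(
            spec.grid_shape)
    source = np.clip(source, 0.0, None)
    target = lv.intensity * lv.brain_mask
    return ImagePair(source=source.astype(np.float32),
                     target=target.astype(np.float32),
                     brain_mask=lv.brain_mask.astype(np.uint8),
                     modality=spec.modality, spec=spec, profile=profile)


def _jittered_spec(modality, grid_shape, voxel_size, noise_sigma, rng, seed):
    base = default_spec(modality, grid_shape, voxel_size, seed=seed)
    axes = tuple(a * rng.uniform(0.9, 1.1) for a in base.brain_axes)
    tissues = {k: v * rng.uniform(0.9, 1.1)
               for k, v in base.tissue_intensities.items()}
    return default_spec(
        modality, grid_shape, voxel_size, seed=seed,
        brain_axes=axes,
        tissue_intensities=tissues,
        shell_intensity=base.shell_intensity * rng.uniform(0.9, 1.1),
        noise_sigma=noise_sigma,
    )


def _jittered_profile(grid_shape, voxel_size, rng):
    base = default_profile(grid_shape, voxel_size)
    nx, ny, _ = grid_shape
    center = (base.coil_center[0] + rng.uniform(-0.04, 0.04) * nx,
              base.coil_center[1] + rng.uniform(-0.04, 0.04) * ny,
              base.coil_center[2])
    return CoilProfile(coil_center=center,
                       coil_radius=base.coil_radius * rng.uniform(0.9, 1.1),
                       floor=base.floor)


def make_dataset(n_ge: int, n_se: int, test_fraction: float, seed: int,
                 grid_shape=(64, 64, 16), voxel_size=(0.3, 0.3, 0.5),
                 noise_sigma: float = 0.05) -> Dataset:
    """Generate a jittered cohort of pairs and split it into train/test.

    Per-phantom geometry, intensities and coil placement are jittered by
    +/-10% from a seeded RNG.  The test set holds
    ``round(n * test_fraction)`` randomly chosen pairs (at least one per
    side), mirroring the roughly-10%-for-testing protocol.
    """
    n = n_ge + n_se
    if n < 2:
        raise ValueError("need at least two pairs to split")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = ss.generate_state(n).astype(np.int64) % (2 ** 31)
    modalities = [GE] * n_ge + [SE] * n_se
    pairs = []
    for i, modality in enumerate(modalities):
        spec = _jittered_spec(modality, grid_shape, voxel_size, noise_sigma,
                              rng, int(child_seeds[i]))
        profile = _jittered_profile(grid_shape, voxel_size, rng)
        pairs.append(make_pair(spec, profile))
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    test_idx = set(rng.choice(n, size=n_test, replace=False).tolist())
    if not test_idx:
        raise ValueError("test split is empty")
    split = ["test" if i in test_idx else "train" for i in range(n)]
    composition = {
        s: {m: sum(1 for p, sp in zip(pairs, split)
                   if sp == s and p.modality == m)
            for m in (GE, SE)}
        for s in ("train", "test")
    }
    return Dataset(pairs=pairs, split=split, composition=composition)


def save_dataset(dataset: Dataset, out_dir) -> None:
    """Write each pair as source/target/mask NIfTI plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for i, (pair, split) in enumerate(zip(dataset.pairs, dataset.split)):
        stem = f"pair{i:04d}"
        vs = pair.spec.voxel_size if pair.spec else (1.0, 1.0, 1.0)
        for kind, arr in (("source", pair.source), ("target", pair.target),
                          ("mask", pair.brain_mask.astype(np.float32))):
            write_volume(Volume(arr, voxel_size=vs),
                         out_dir / f"{stem}_{kind}.nii.gz")
        sidecar = {
            "modality": pair.modality,
            "split": split,
            "spec": pair.spec.to_json() if pair.spec else None,
            "profile": pair.profile.to_json() if pair.profile else None,
        }
        write_sidecar(out_dir / f"{stem}.json", sidecar)
        index.append(stem)
    write_sidecar(out_dir / "dataset.json",
                  {"pairs": index, "composition": dataset.composition})


def load_dataset(in_dir) -> Dataset:
    """Inverse of :func:`save_dataset` (specs are restored from sidecars)."""
    in_dir = Path(in_dir)
    meta = read_sidecar(in_dir / "dataset.json")
    pairs, split = [], []
    for stem in meta["pairs"]:
        side = read_sidecar(in_dir / f"{stem}.json")
        spec = PhantomSpec(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in side["spec"].items()}) \
            if side.get("spec") else None
        prof = CoilProfile(**{k: (tuple(v) if isinstance(v, list) else v)
                              for k, v in side["profile"].items()}) \
            if side.get("profile") else None
        src = read_volume(in_dir / f"{stem}_source.nii.gz").data
        tgt = read_volume(in_dir / f"{stem}_target.nii.gz").data
        msk = read_volume(in_dir / f"{stem}_mask.nii.gz").data > 0.5
        pairs.append(ImagePair(source=src, target=tgt,
                               brain_mask=msk.astype(np.uint8),
                               modality=side["modality"], spec=spec,
                               profile=prof))
        split.append(side["split"])
    return Dataset(pairs=pairs, split=split,
                   composition=meta.get("composition", {}))
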