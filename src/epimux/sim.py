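"""Synthetic multiplex-section generator with per-pixel epitope ground truth.

The simulator emulates 20x slide scans of alpha-synucleinopathy tissue:
a smooth tissue region on glass, populated with aggregate classes drawn from
the PD / MSA aggregate taxonomy.  Each class carries a shape model, a size
distribution and a per-epitope composition rule: either one membership
vector over (Nterm, pS129, Cterm) for the whole object, or a partitioned
rule assigning different vectors to sub-structures (core vs periphery of a
shelled Lewy body or glial cytoplasmic inclusion; interlaced single-epitope
filaments of a web-like neuronal inclusion).

Rendering follows the standard fluorescence camera model: per-channel signal
plus background, Gaussian point-spread blur, Poisson shot noise and additive
Gaussian read noise, quantized to 8 or 16 bits.  The pre-blur membership
rasters are returned alongside the rendered images as the ground-truth
oracle for segmentation-recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology

from .io import EPITOPES, MultiplexSection, SectionMetadata, quant_record_rows
from .quantify import QuantRecord, quantify_section
from .segment import EpitopeMaskSet

SHAPE_MODELS = ("punctate", "neurite", "shell_body", "filament_web",
                "irregular_cluster")

PRESETS = ("PD_like", "MSA_medulla_like", "MSA_cerebellum_like",
           "MSA_ION_like", "control_like")

_PRESET_GROUP = {
    "PD_like": ("PD", "substantia_nigra"),
    "MSA_medulla_like": ("MSA", "medulla"),
    "MSA_cerebellum_like": ("MSA", "cerebellum"),
    "MSA_ION_like": ("MSA", "ION"),
    "control_like": ("control", "substantia_nigra"),
}


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


def _check_membership(vec: Sequence[int], where: str) -> tuple[int, int, int]:
    vec = tuple(int(v) for v in vec)
    if len(vec) != 3 or any(v not in (0, 1) for v in vec) or not any(vec):
        raise ConfigurationError(
            f"{where}: membership vector must be nonzero in {{0,1}}^3, got {vec}"
        )
    return vec


@dataclass(frozen=True)
class SizeDist:
    """Truncated-normal object size in micrometres (diameter, or length for
    neurite-like shapes)."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not 0 < self.min <= self.max:
            raise ConfigurationError("size bounds must satisfy 0 < min <= max")

    def sample(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), self.min, self.max))


@dataclass(frozen=True)
class CompositionRule:
    """Per-epitope membership of an aggregate class.

    Exactly one of the three forms is set:

    * ``membership`` — one vector for the whole object;
    * ``core`` + ``periphery`` — shelled bodies with distinct rim membership;
    * ``filament_choices`` — web-like inclusions whose individual filaments
      each draw one vector from this set.
    """

    membership: tuple[int, int, int] | None = None
    core: tuple[int, int, int] | None = None
    periphery: tuple[int, int, int] | None = None
    filament_choices: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.membership is not None:
            object.__setattr__(self, "membership",
                               _check_membership(self.membership, "membership"))
        if self.core is not None or self.periphery is not None:
            if self.core is None or self.periphery is None:
                raise ConfigurationError("core and periphery must both be set")
            object.__setattr__(self, "core", _check_membership(self.core, "core"))
            object.__setattr__(self, "periphery",
                               _check_membership(self.periphery, "periphery"))
        if self.filament_choices is not None:
            object.__setattr__(self, "filament_choices", tuple(
                _check_membership(v, "filament_choices")
                for v in self.filament_choices
            ))
        forms = [self.membership is not None, self.core is not None,
                 self.filament_choices is not None]
        if sum(forms) != 1:
            raise ConfigurationError("exactly one composition form must be set")

    def channels_present(self) -> tuple[int, int, int]:
        """Union of all membership vectors the rule can emit."""
        vecs = []
        if self.membership is not None:
            vecs.append(self.membership)
        if self.core is not None:
            vecs.extend([self.core, self.periphery])
        if self.filament_choices is not None:
            vecs.extend(self.filament_choices)
        return tuple(int(any(v[i] for v in vecs)) for i in range(3))


@dataclass(frozen=True)
class AggregateClassSpec:
    """One aggregate class of the taxonomy: shape, size, composition."""

    name: str
    shape_model: str
    size_um: SizeDist
    composition: CompositionRule
    intensity_scale: tuple[float, float, float]
    abundance_weight: float

    def __post_init__(self) -> None:
        if self.shape_model not in SHAPE_MODELS:
            raise ConfigurationError(f"unknown shape model {self.shape_model!r}")
        if self.abundance_weight < 0:
            raise ConfigurationError("abundance_weight must be >= 0")
        if self.shape_model == "shell_body" and self.composition.core is None:
            raise ConfigurationError("shell_body needs a core/periphery rule")
        if (self.shape_model == "filament_web"
                and self.composition.filament_choices is None):
            raise ConfigurationError("filament_web needs filament_choices")


@dataclass(frozen=True)
class NoiseParams:
    poisson_gain: float = 1.0
    read_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.poisson_gain < 0 or self.read_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")


@dataclass(frozen=True)
class TissueGeometry:
    """Smooth random tissue blob: coverage fraction and boundary roughness
    (the smoothing scale of the underlying noise field, in px)."""

    coverage: float = 0.55
    smooth_sigma_px: float = 40.0

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ConfigurationError("tissue coverage must be in (0, 1]")


@dataclass(frozen=True)
class SectionSimConfig:
    """Full specification of one synthetic section."""

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.325
    channel_order: tuple[str, str, str] = EPITOPES
    tissue_geometry: TissueGeometry = field(default_factory=TissueGeometry)
    classes: tuple[AggregateClassSpec, ...] = ()
    total_aggregate_count: int = 0
    background_level: tuple[float, float, float] = (150.0, 150.0, 150.0)
    psf_sigma_px: float = 0.8
    noise: NoiseParams = field(default_factory=NoiseParams)
    bit_depth: int = 16
    seed: int = 0
    preset_name: str | None = None
    #: optional 3x3 spectral mixing matrix (row = detected channel, col =
    #: source channel) applied after the PSF and before noise; None = no
    #: bleed-through (the default: no unmixing step exists downstream)
    bleed_matrix: tuple[tuple[float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigurationError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if (len(self.channel_order) != 3
                or len(set(self.channel_order)) != 3):
            raise ConfigurationError("channel_order needs 3 distinct labels")
        if self.total_aggregate_count < 0:
            raise ConfigurationError("total_aggregate_count must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if self.psf_sigma_px < 0:
            raise ConfigurationError("psf_sigma_px must be >= 0")
        if self.total_aggregate_count > 0 and not self.classes:
            raise ConfigurationError("aggregates requested but no classes given")


@dataclass
class AggregateRecord:
    """One placed aggregate: id, class, and per-part pixel coordinates with
    their membership vectors (a part is a disjoint sub-structure)."""

    aggregate_id: int
    class_name: str
    parts: list[tuple[np.ndarray, np.ndarray, tuple[int, int, int]]]

    @property
    def area_px(self) -> int:
        return int(sum(len(rr) for rr, _, _ in self.parts))

    @property
    def membership_union(self) -> tuple[int, int, int]:
        return tuple(int(any(m[i] for _, _, m in self.parts)) for i in range(3))


@dataclass
class GroundTruthSection:
    """Pre-blur per-channel membership masks and per-aggregate records."""

    true_masks: dict[str, np.ndarray]
    tissue_mask: np.ndarray
    aggregates: list[AggregateRecord]
    placement_failures: int = 0

    def validate(self) -> None:
        """Check the structural invariants of the ground truth."""
        union = np.zeros_like(self.tissue_mask)
        for name, m in self.true_masks.items():
            if np.any(m & ~self.tissue_mask):
                raise AssertionError(f"true mask {name} leaves the tissue")
            union |= m
        occ = np.zeros_like(self.tissue_mask)
        agg_union = np.zeros_like(self.tissue_mask)
        ids = set()
        for agg in self.aggregates:
            if agg.aggregate_id in ids:
                raise AssertionError("duplicate aggregate id")
            ids.add(agg.aggregate_id)
            for rr, cc, _ in agg.parts:
                if occ[rr, cc].any():
                    raise AssertionError("aggregate pixel sets overlap")
                occ[rr, cc] = True
                agg_union[rr, cc] = True
        if not np.array_equal(agg_union, union):
            raise AssertionError(
                "union of aggregate pixels differs from union of true masks"
            )


# ---------------------------------------------------------------------------
# Preset catalogue
# ---------------------------------------------------------------------------

def _cls(name, shape, mean, sd, lo, hi, comp, scale, weight):
    return AggregateClassSpec(
        name=name, shape_model=shape, size_um=SizeDist(mean, sd, lo, hi),
        composition=comp, intensity_scale=scale, abundance_weight=weight,
    )


def _uniform(vec):
    return CompositionRule(membership=vec)


def build_preset(preset_name: str) -> SectionSimConfig:
    """Return a fully populated config for one of the named study presets.

    ``PD_like`` carries shelled Lewy bodies (all three epitopes, pS129/
    C-terminus-enriched periphery), pS129-exclusive neurites, and the
    N-terminus-exclusive punctate / perinuclear / glial classes.  The MSA
    presets carry shelled glial cytoplasmic inclusions (mixed core,
    C-terminus-positive rim) and an N-terminus-exclusive punctate neuronal
    class; ``MSA_ION_like`` adds web-like neuronal inclusions made of
    interlaced filaments that are individually N- or C-terminus exclusive
    and never pS129-positive.  ``control_like`` places no aggregates.
    """
    if preset_name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset_name!r}; choose from {PRESETS}"
        )

    gci_core = CompositionRule(core=(1, 1, 1), periphery=(0, 0, 1))
    gci_nop = CompositionRule(core=(1, 0, 1), periphery=(0, 0, 1))
    lewy_body = CompositionRule(core=(1, 1, 1), periphery=(0, 1, 1))
    web_nc = CompositionRule(filament_choices=((1, 0, 0), (0, 0, 1)))

    if preset_name == "PD_like":
        classes = (
            _cls("lysosomal_punctate", "punctate", 1.4, 0.3, 0.9, 2.2,
                 _uniform((1, 0, 0)), (1800, 0, 0), 0.30),
            _cls("perinuclear", "punctate", 2.6, 0.5, 1.6, 4.0,
                 _uniform((1, 0, 0)), (1600, 0, 0), 0.15),
            _cls("glial_nterm", "irregular_cluster", 8.0, 1.5, 5.0, 12.0,
                 _uniform((1, 0, 0)), (1400, 0, 0), 0.14),
            _cls("ps129_neurite", "neurite", 15.0, 4.0, 8.0, 25.0,
                 _uniform((0, 1, 0)), (0, 1500, 0), 0.15),
            _cls("lewy_neurite", "neurite", 20.0, 5.0, 10.0, 30.0,
                 _uniform((1, 1, 1)), (1500, 1200, 1500), 0.12),
            _cls("lewy_body", "shell_body", 10.0, 2.0, 6.0, 14.0,
                 lewy_body, (1700, 1500, 1700), 0.08),
            _cls("cterm_thread", "neurite", 10.0, 3.0, 6.0, 18.0,
                 _uniform((0, 0, 1)), (0, 0, 1500), 0.06),
        )
        count = 40
    elif preset_name == "MSA_medulla_like":
        classes = (
            _cls("gci", "shell_body", 8.0, 1.5, 5.0, 12.0,
                 gci_core, (1600, 1100, 1700), 0.25),
            _cls("gci_ps129_negative", "shell_body", 8.0, 1.5, 5.0, 12.0,
                 gci_nop, (1600, 0, 1700), 0.25),
            _cls("neuronal_punctate", "punctate", 1.4, 0.3, 0.9, 2.2,
                 _uniform((1, 0, 0)), (1800, 0, 0), 0.18),
            _cls("nci_filament_web", "filament_web", 12.0, 2.0, 8.0, 16.0,
                 web_nc, (1500, 0, 1500), 0.20),
            _cls("nc_thread", "neurite", 12.0, 3.0, 6.0, 20.0,
                 _uniform((1, 0, 1)), (1500, 0, 1500), 0.12),
        )
        count = 45
    elif preset_name == "MSA_cerebellum_like":
        classes = (
            _cls("gci", "shell_body", 8.0, 1.5, 5.0, 12.0,
                 gci_core, (1600, 1100, 1700), 0.38),
            _cls("gci_ps129_negative", "shell_body", 8.0, 1.5, 5.0, 12.0,
                 gci_nop, (1600, 0, 1700), 0.34),
            _cls("neuronal_punctate", "punctate", 1.4, 0.3, 0.9, 2.2,
                 _uniform((1, 0, 0)), (1800, 0, 0), 0.08),
            _cls("nc_thread", "neurite", 12.0, 3.0, 6.0, 20.0,
                 _uniform((1, 0, 1)), (1500, 0, 1500), 0.12),
            _cls("nci_filament_web", "filament_web", 12.0, 2.0, 8.0, 16.0,
                 web_nc, (1500, 0, 1500), 0.08),
        )
        count = 40
    elif preset_name == "MSA_ION_like":
        classes = (
            _cls("nci_filament_web", "filament_web", 14.0, 2.5, 9.0, 18.0,
                 web_nc, (1500, 0, 1500), 0.62),
            _cls("neuronal_punctate", "punctate", 1.4, 0.3, 0.9, 2.2,
                 _uniform((1, 0, 0)), (1800, 0, 0), 0.20),
            _cls("gci", "shell_body", 8.0, 1.5, 5.0, 12.0,
                 gci_core, (1600, 1100, 1700), 0.08),
            _cls("nc_thread", "neurite", 12.0, 3.0, 6.0, 20.0,
                 _uniform((1, 0, 1)), (1500, 0, 1500), 0.10),
        )
        count = 40
    else:  # control_like
        classes = ()
        count = 0

    return SectionSimConfig(classes=classes, total_aggregate_count=count,
                            preset_name=preset_name)


# ---------------------------------------------------------------------------
# Shape rasterizers (local canvases; parts are mutually disjoint)
# ---------------------------------------------------------------------------

def _disk(radius_px: float) -> np.ndarray:
    r = max(1.0, radius_px)
    n = int(np.ceil(r))
    y, x = np.ogrid[-n:n + 1, -n:n + 1]
    return (x * x + y * y) <= r * r


def _walk(rng: np.random.Generator, length_px: float, turn_sd: float = 0.3,
          step: float = 2.0) -> np.ndarray:
    """Smoothed random-walk polyline as integer points around the origin."""
    n_steps = max(2, int(length_px / step))
    theta = rng.uniform(0, 2 * np.pi)
    pts = [(0.0, 0.0)]
    for _ in range(n_steps):
        theta += rng.normal(0, turn_sd)
        r0, c0 = pts[-1]
        pts.append((r0 + step * np.sin(theta), c0 + step * np.cos(theta)))
    return np.asarray(pts)


def _raster_polyline(pts: np.ndarray, width_px: int) -> np.ndarray:
    """Rasterize a polyline into a tight canvas, dilated to 1-2 px width."""
    pts = np.round(pts - pts.min(axis=0)).astype(int)
    pad = 2
    h = pts[:, 0].max() + 2 * pad + 1
    w = pts[:, 1].max() + 2 * pad + 1
    canvas = np.zeros((h, w), bool)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = skdraw.line(r0 + pad, c0 + pad, r1 + pad, c1 + pad)
        canvas[rr, cc] = True
    if width_px >= 2:
        canvas = morphology.dilation(canvas, np.ones((2, 2), bool))
    return canvas


def _render_shape(
    spec: AggregateClassSpec, rng: np.random.Generator, pixel_size_um: float
) -> list[tuple[np.ndarray, tuple[int, int, int]]]:
    """Return disjoint (local boolean mask, membership) parts for one object."""
    size_px = spec.size_um.sample(rng) / pixel_size_um
    comp = spec.composition

    if spec.shape_model == "punctate":
        return [(_disk(size_px / 2), comp.membership)]

    if spec.shape_model == "neurite":
        pts = _walk(rng, size_px)
        width = int(rng.integers(1, 3))
        return [(_raster_polyline(pts, width), comp.membership)]

    if spec.shape_model == "shell_body":
        radius = max(3.0, size_px / 2)
        rel_thick = max(0.15, 1.5 / radius)
        outer = _disk(radius)
        core = np.zeros_like(outer)
        inner = _disk(radius * (1 - rel_thick))
        off = (outer.shape[0] - inner.shape[0]) // 2
        core[off:off + inner.shape[0], off:off + inner.shape[1]] = inner
        rim = outer & ~core
        return [(core, comp.core), (rim, comp.periphery)]

    if spec.shape_model == "filament_web":
        radius = max(5.0, size_px / 2)
        envelope = _disk(radius)
        h, w = envelope.shape
        ctr = h // 2
        n_fil = int(rng.integers(5, 13))
        claimed = np.zeros_like(envelope)
        parts = []
        for _ in range(n_fil):
            # chord-like filament: start on the rim, head across the soma
            ang = rng.uniform(0, 2 * np.pi)
            start = np.array([ctr + 0.9 * radius * np.sin(ang),
                              ctr + 0.9 * radius * np.cos(ang)])
            heading = ang + np.pi + rng.normal(0, 0.4)
            pts = [start.copy()]
            for _ in range(int(2.2 * radius / 1.5)):
                heading += rng.normal(0, 0.25)
                pts.append(pts[-1] + 1.5 * np.array(
                    [np.sin(heading), np.cos(heading)]))
            pts = np.asarray(pts)
            fil = np.zeros_like(envelope)
            ipts = np.round(pts).astype(int)
            ipts = ipts[(ipts[:, 0] >= 0) & (ipts[:, 0] < h)
                        & (ipts[:, 1] >= 0) & (ipts[:, 1] < w)]
            if len(ipts) < 2:
                continue
            for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
                rr, cc = skdraw.line(r0, c0, r1, c1)
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                fil[rr[keep], cc[keep]] = True
            if rng.random() < 0.5:
                fil = morphology.dilation(fil, np.ones((2, 2), bool))
            fil &= envelope & ~claimed
            # crossings with already-claimed filaments can shatter this one;
            # keep only coherent pieces so no tiny fragments enter the truth
            lab, n_lab = ndimage.label(fil, structure=np.ones((3, 3)))
            if n_lab:
                sizes = np.bincount(lab.ravel())
                fil = sizes[lab] >= 6
                fil &= lab > 0
            if fil.sum() < 6:
                continue
            membership = comp.filament_choices[
                int(rng.integers(len(comp.filament_choices)))
            ]
            claimed |= fil
            parts.append((fil, membership))
        if not parts:  # degenerate draw; fall back to one straight filament
            fil = np.zeros_like(envelope)
            rr, cc = skdraw.line(2, ctr, h - 3, ctr)
            fil[rr, cc] = True
            parts = [(fil & envelope, comp.filament_choices[0])]
        return parts

    if spec.shape_model == "irregular_cluster":
        radius = max(4.0, size_px / 2)
        envelope = _disk(radius)
        h, w = envelope.shape
        ctr = h // 2
        void = np.zeros_like(envelope)
        vd = _disk(0.3 * radius)
        off = ctr - vd.shape[0] // 2
        void[off:off + vd.shape[0], off:off + vd.shape[1]] = vd
        cluster = np.zeros_like(envelope)
        for _ in range(int(rng.integers(4, 9))):
            sub = _disk(rng.uniform(0.3, 0.5) * radius)
            dr, dc = rng.uniform(-0.55 * radius, 0.55 * radius, 2)
            r0 = int(ctr + dr - sub.shape[0] // 2)
            c0 = int(ctr + dc - sub.shape[1] // 2)
            rs = slice(max(r0, 0), min(r0 + sub.shape[0], h))
            cs = slice(max(c0, 0), min(c0 + sub.shape[1], w))
            cluster[rs, cs] |= sub[rs.start - r0:rs.stop - r0,
                                   cs.start - c0:cs.stop - c0]
        cluster &= envelope & ~void
        if not cluster.any():
            cluster = _disk(radius / 2)
        return [(cluster, comp.membership)]

    raise ConfigurationError(spec.shape_model)


# ---------------------------------------------------------------------------
# Section simulation
# ---------------------------------------------------------------------------

def _tissue_blob(rng: np.random.Generator, shape: tuple[int, int],
                 geom: TissueGeometry) -> np.ndarray:
    if geom.coverage >= 1.0:
        return np.ones(shape, bool)
    noise = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(noise, sigma=geom.smooth_sigma_px,
                                     mode="reflect")
    thr = np.quantile(fieldv, 1.0 - geom.coverage)
    mask = fieldv >= thr
    mask = morphology.closing(mask, morphology.disk(5))
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(sizes)) + 1)
    return mask


def _apportion(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of `total` over `weights`."""
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ConfigurationError("abundance weights sum to zero")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:rem]] += 1
    return counts


def class_counts(config: SectionSimConfig) -> dict[str, int]:
    """Deterministic per-class aggregate counts implied by the config."""
    if config.total_aggregate_count == 0 or not config.classes:
        return {c.name: 0 for c in config.classes}
    counts = _apportion(config.total_aggregate_count,
                        [c.abundance_weight for c in config.classes])
    return {c.name: int(k) for c, k in zip(config.classes, counts)}


def simulate_section(
    config: SectionSimConfig,
    metadata: SectionMetadata | None = None,
) -> tuple[MultiplexSection, GroundTruthSection]:
    """Render one synthetic section and its ground truth.

    Deterministic for a fixed config (the seed lives in the config).  Objects
    are placed fully inside the tissue region and never overlap a previously
    placed object; an object that cannot be placed after a bounded number of
    attempts is skipped with a warning and counted in
    ``GroundTruthSection.placement_failures``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.height_px, config.width_px)
    tissue = _tissue_blob(rng, shape, config.tissue_geometry)

    true_masks = {name: np.zeros(shape, bool) for name in config.channel_order}
    occupied = np.zeros(shape, bool)
    aggregates: list[AggregateRecord] = []
    failures = 0

    counts = class_counts(config)
    tissue_rows, tissue_cols = np.nonzero(tissue)
    next_id = 0
    for spec in config.classes:
        for _ in range(counts[spec.name]):
            placed = False
            for _attempt in range(100):
                parts = _render_shape(spec, rng, config.pixel_size_um)
                full = np.zeros_like(parts[0][0])
                for m, _ in parts:
                    full |= m
                h, w = full.shape
                idx = int(rng.integers(len(tissue_rows)))
                r0 = tissue_rows[idx] - h // 2
                c0 = tissue_cols[idx] - w // 2
                if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
                    continue
                frr, fcc = np.nonzero(full)
                arr, acc = frr + r0, fcc + c0
                if not tissue[arr, acc].all() or occupied[arr, acc].any():
                    continue
                rec_parts = []
                for m, membership in parts:
                    prr, pcc = np.nonzero(m)
                    if len(prr) == 0:
                        continue
                    prr, pcc = prr + r0, pcc + c0
                    rec_parts.append((prr, pcc, membership))
                    for ch_i, name in enumerate(config.channel_order):
                        if membership[ch_i]:
                            true_masks[name][prr, pcc] = True
                occupied[arr, acc] = True
                aggregates.append(AggregateRecord(
                    aggregate_id=next_id, class_name=spec.name,
                    parts=rec_parts))
                next_id += 1
                placed = True
                break
            if not placed:
                failures += 1
    if failures:
        warnings.warn(
            f"{failures} aggregate(s) could not be placed inside tissue",
            stacklevel=2,
        )

    # render channels: signal + tissue background -> PSF -> noise -> quantize
    max_val = 2 ** config.bit_depth - 1
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    expected: list[np.ndarray] = []
    for ch_i, name in enumerate(config.channel_order):
        img = np.zeros(shape, np.float64)
        for agg in aggregates:
            spec = next(c for c in config.classes if c.name == agg.class_name)
            for prr, pcc, membership in agg.parts:
                if membership[ch_i]:
                    img[prr, pcc] = spec.intensity_scale[ch_i]
        img += config.background_level[ch_i] * tissue
        if config.psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, sigma=config.psf_sigma_px,
                                          mode="reflect")
        expected.append(img)
    if config.bleed_matrix is not None:
        mix = np.asarray(config.bleed_matrix, np.float64)
        if mix.shape != (3, 3):
            raise ConfigurationError("bleed_matrix must be 3x3")
        stacked = np.stack(expected)
        expected = list(np.tensordot(mix, stacked, axes=1))
    channels: dict[str, np.ndarray] = {}
    for img, name in zip(expected, config.channel_order):
        gain = config.noise.poisson_gain
        if gain > 0:
            img = rng.poisson(np.maximum(img, 0) * gain) / gain
        if config.noise.read_sd > 0:
            img = img + rng.normal(0, config.noise.read_sd, shape)
        channels[name] = np.clip(np.rint(img), 0, max_val).astype(dtype)

    if metadata is None and config.preset_name:
        group, region = _PRESET_GROUP[config.preset_name]
        metadata = SectionMetadata(case_id="sim", group=group, region=region)
    section = MultiplexSection(
        channels=channels, pixel_size_um=config.pixel_size_um,
        metadata=metadata or SectionMetadata(),
        tissue_mask=tissue.copy(),
    )
    truth = GroundTruthSection(
        true_masks=true_masks, tissue_mask=tissue,
        aggregates=aggregates, placement_failures=failures,
    )
    return section, truth


def true_quant(
    gt: GroundTruthSection,
    metadata: SectionMetadata | None = None,
    pixel_size_um: float = 1.0,
) -> QuantRecord:
    """Quantify the noise-free ground truth with the shared mask algebra.

    This is the oracle for segmentation-recovery tests: it routes the true
    membership masks through the same Venn/percentage code as the measured
    masks, so the two records are directly comparable.
    """
    maskset = EpitopeMaskSet(
        masks={k: v.copy() for k, v in gt.true_masks.items()},
        tissue_mask=gt.tissue_mask,
    )
    return quantify_section(maskset, metadata=metadata,
                            pixel_size_um=pixel_size_um)


def simulate_cohort(
    config: SectionSimConfig,
    n_cases: int,
    base_seed: int,
    dispersion: float = 0.3,
) -> tuple[list[MultiplexSection], list[GroundTruthSection], pd.DataFrame]:
    """Simulate a cohort of cases with between-case abundance variability.

    Case ``i`` (1-based) uses seed ``base_seed + i``.  Each case's class
    abundance weights are scaled by independent log-normal multipliers
    (``sigma = dispersion``); at ``dispersion = 0`` every case shares the
    config's exact class counts and case ``i`` is identical to
    ``simulate_section`` run with seed ``base_seed + i``.

    Returns the rendered sections, ground truths, and a long-format table of
    the true (noise-free) quantities per case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    group, region = _PRESET_GROUP.get(
        config.preset_name or "", ("control", "unspecified")
    )
    sections, truths, rows = [], [], []
    for i in range(1, n_cases + 1):
        seed_i = base_seed + i
        rng_i = np.random.default_rng(seed_i)
        mult = np.exp(rng_i.normal(0.0, dispersion, len(config.classes)))
        classes_i = tuple(
            replace(c, abundance_weight=c.abundance_weight * m)
            for c, m in zip(config.classes, mult)
        )
        config_i = replace(config, classes=classes_i, seed=seed_i)
        md = SectionMetadata(case_id=f"case_{i:02d}", group=group,
                             region=region)
        section, truth = simulate_section(config_i, metadata=md)
        record = true_quant(truth, metadata=md,
                            pixel_size_um=config.pixel_size_um)
        rows.extend(quant_record_rows(record))
        sections.append(section)
        truths.append(truth)
    table = pd.DataFrame(
        rows, columns=["case_id", "group", "region", "measure", "value"]
    )
    return sections, truths, table


# ---------------------------------------------------------------------------
# Config serialization (structured text, YAML)
# ---------------------------------------------------------------------------

def config_to_dict(config: SectionSimConfig) -> dict:
    def rule(c: CompositionRule) -> dict:
        d = {}
        if c.membership is not None:
            d["membership"] = list(c.membership)
        if c.core is not None:
            d["core"] = list(c.core)
            d["periphery"] = list(c.periphery)
        if c.filament_choices is not None:
            d["filament_choices"] = [list(v) for v in c.filament_choices]
        return d

    return {
        "width_px": config.width_px,
        "height_px": config.height_px,
        "pixel_size_um": config.pixel_size_um,
        "channel_order": list(config.channel_order),
        "tissue_geometry": {
            "coverage": config.tissue_geometry.coverage,
            "smooth_sigma_px": config.tissue_geometry.smooth_sigma_px,
        },
        "classes": [
            {
                "name": c.name,
                "shape_model": c.shape_model,
                "size_um": {"mean": c.size_um.mean, "sd": c.size_um.sd,
                            "min": c.size_um.min, "max": c.size_um.max},
                "composition": rule(c.composition),
                "intensity_scale": list(c.intensity_scale),
                "abundance_weight": c.abundance_weight,
            }
            for c in config.classes
        ],
        "total_aggregate_count": config.total_aggregate_count,
        "background_level": list(config.background_level),
        "psf_sigma_px": config.psf_sigma_px,
        "noise": {"poisson_gain": config.noise.poisson_gain,
                  "read_sd": config.noise.read_sd},
        "bit_depth": config.bit_depth,
        "seed": config.seed,
        "preset_name": config.preset_name,
        "bleed_matrix": ([list(r) for r in config.bleed_matrix]
                         if config.bleed_matrix is not None else None),
    }


def config_from_dict(d: dict) -> SectionSimConfig:
    def rule(rd: dict) -> CompositionRule:
        return CompositionRule(
            membership=tuple(rd["membership"]) if "membership" in rd else None,
            core=tuple(rd["core"]) if "core" in rd else None,
            periphery=tuple(rd["periphery"]) if "periphery" in rd else None,
            filament_choices=(
                tuple(tuple(v) for v in rd["filament_choices"])
                if "filament_choices" in rd else None
            ),
        )

    classes = tuple(
        AggregateClassSpec(
            name=c["name"], shape_model=c["shape_model"],
            size_um=SizeDist(**c["size_um"]),
            composition=rule(c["composition"]),
            intensity_scale=tuple(c["intensity_scale"]),
            abundance_weight=c["abundance_weight"],
        )
        for c in d.get("classes", [])
    )
    return SectionSimConfig(
        width_px=d.get("width_px", 512),
        height_px=d.get("height_px", 512),
        pixel_size_um=d.get("pixel_size_um", 0.325),
        channel_order=tuple(d.get("channel_order", EPITOPES)),
        tissue_geometry=TissueGeometry(**d.get("tissue_geometry", {})),
        classes=classes,
        total_aggregate_count=d.get("total_aggregate_count", 0),
        background_level=tuple(d.get("background_level", (150.0,) * 3)),
        psf_sigma_px=d.get("psf_sigma_px", 0.8),
        noise=NoiseParams(**d.get("noise", {})),
        bit_depth=d.get("bit_depth", 16),
        seed=d.get("seed", 0),
        preset_name=d.get("preset_name"),
        bleed_matrix=(tuple(tuple(r) for r in d["bleed_matrix"])
                      if d.get("bleed_matrix") else None),
    )


def save_config(config: SectionSimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SectionSimConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
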