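"""Venn-compartment mask algebra and the epitope-specific area statistics.

Three binary epitope masks induce seven disjoint pixel compartments: each
single-epitope exclusive region (N_only, P_only, C_only), each pairwise-only
overlap (NP_only, NC_only, PC_only) and the triple overlap (NPC).  From these
the pipeline's headline statistics follow:

* pathology load       = 100 * union / tissue area
* total (individual)   = 100 * area(one epitope mask, incl. overlap) / union
* unique epitope area  = 100 * exclusive area of one epitope / union

All arithmetic is on integer pixel counts; conservation (the seven
compartments partition the union) is asserted at run time on every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .io import EPITOPES, SectionMetadata
from .segment import EpitopeMaskSet

#: Map epitope label -> letter used in compartment names.
_LETTER = {"Nterm": "N", "pS129": "P", "Cterm": "C"}


@dataclass(frozen=True)
class VennAreas:
    """Pixel counts of the 7 disjoint compartments plus union and tissue."""

    N_only: int
    P_only: int
    C_only: int
    NP_only: int
    NC_only: int
    PC_only: int
    NPC: int
    union_px: int
    tissue_px: int

    def __post_init__(self) -> None:
        counts = (self.N_only, self.P_only, self.C_only,
                  self.NP_only, self.NC_only, self.PC_only, self.NPC)
        if any(c < 0 for c in counts):
            raise ValueError("negative compartment count")
        if sum(counts) != self.union_px:
            raise AssertionError(
                "compartment counts do not sum to the union count"
            )
        if self.union_px > self.tissue_px:
            raise AssertionError("union exceeds tissue area")

    def epitope_total(self, epitope: str) -> int:
        """Total pixels of one epitope's mask, overlap included."""
        if epitope == "Nterm":
            return self.N_only + self.NP_only + self.NC_only + self.NPC
        if epitope == "pS129":
            return self.P_only + self.NP_only + self.PC_only + self.NPC
        if epitope == "Cterm":
            return self.C_only + self.NC_only + self.PC_only + self.NPC
        raise KeyError(epitope)

    def epitope_unique(self, epitope: str) -> int:
        return {"Nterm": self.N_only, "pS129": self.P_only,
                "Cterm": self.C_only}[epitope]


@dataclass
class QuantRecord:
    """Per-section quantification: pathology load and epitope percentages."""

    venn: VennAreas
    pathology_load_pct: float
    total_pct: dict[str, float]
    unique_pct: dict[str, float]
    metadata: SectionMetadata = field(default_factory=SectionMetadata)
    pixel_size_um: float = 1.0
    zero_union: bool = False

    def __post_init__(self) -> None:
        # mass-balance invariants, enforced on every construction
        assert 0.0 <= self.pathology_load_pct <= 100.0
        for epi in EPITOPES:
            u, t = self.unique_pct[epi], self.total_pct[epi]
            assert 0.0 <= u <= t + 1e-9 <= 100.0 + 1e-9, (
                f"unique > total for {epi}: {u} > {t}"
            )
        if self.venn.union_px > 0:
            assert sum(self.total_pct.values()) >= 100.0 - 1e-9
        assert sum(self.unique_pct.values()) <= 100.0 + 1e-9

    def area_um2(self, compartment: str) -> float:
        """Compartment area in square micrometres."""
        return getattr(self.venn, compartment) * self.pixel_size_um ** 2


def venn_areas(maskset: EpitopeMaskSet) -> VennAreas:
    """Classify every pixel into one of the 7 disjoint compartments."""
    n = maskset.masks["Nterm"]
    p = maskset.masks["pS129"]
    c = maskset.masks["Cterm"]
    tissue = maskset.tissue_mask
    if not (n.shape == p.shape == c.shape == tissue.shape):
        raise ValueError("mask shapes differ")
    for name, m in maskset.masks.items():
        if np.any(m & ~tissue):
            raise ValueError(f"mask {name!r} extends outside the tissue mask")
    union = n | p | c
    areas = VennAreas(
        N_only=int(np.count_nonzero(n & ~p & ~c)),
        P_only=int(np.count_nonzero(~n & p & ~c)),
        C_only=int(np.count_nonzero(~n & ~p & c)),
        NP_only=int(np.count_nonzero(n & p & ~c)),
        NC_only=int(np.count_nonzero(n & ~p & c)),
        PC_only=int(np.count_nonzero(~n & p & c)),
        NPC=int(np.count_nonzero(n & p & c)),
        union_px=int(np.count_nonzero(union)),
        tissue_px=int(np.count_nonzero(tissue)),
    )
    return areas


def quantify_section(
    maskset: EpitopeMaskSet,
    metadata: SectionMetadata | None = None,
    pixel_size_um: float = 1.0,
) -> QuantRecord:
    """Compute the pathology-load / total / unique percentages of a section.

    On an empty union (e.g. control tissue) all percentages-of-union are
    reported as 0 with ``zero_union`` set, so control sections flow through
    cohort tables rather than erroring.
    """
    venn = venn_areas(maskset)
    if venn.tissue_px == 0:
        raise ValueError("tissue area is zero; pathology load undefined")
    load = 100.0 * venn.union_px / venn.tissue_px
    if venn.union_px == 0:
        total = {e: 0.0 for e in EPITOPES}
        unique = {e: 0.0 for e in EPITOPES}
        zero_union = True
    else:
        total = {e: 100.0 * venn.epitope_total(e) / venn.union_px
                 for e in EPITOPES}
        unique = {e: 100.0 * venn.epitope_unique(e) / venn.union_px
                  for e in EPITOPES}
        zero_union = False
    return QuantRecord(
        venn=venn,
        pathology_load_pct=load,
        total_pct=total,
        unique_pct=unique,
        metadata=metadata or SectionMetadata(),
        pixel_size_um=pixel_size_um,
        zero_union=zero_union,
    )


@dataclass
class AggregateProfile:
    """Per-connected-component epitope coverage on the union mask."""

    component_id: int
    area_px: int
    centroid: tuple[float, float]
    coverage: dict[str, float]
    exclusivity: str  # N_exclusive / P_exclusive / C_exclusive / mixed


def aggregate_profiles(
    maskset: EpitopeMaskSet,
    connectivity: int = 8,
    epsilon: float = 0.05,
) -> list[AggregateProfile]:
    """Profile each connected component of the union mask.

    Components are labelled with 4- or 8-connectivity in scan order.  For
    each component the per-channel coverage fraction is the fraction of its
    pixels positive in that channel; the component is ``X_exclusive`` iff
    coverage[X] >= 1 - epsilon while both other coverages are <= epsilon,
    otherwise ``mixed``.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    union = (maskset.masks["Nterm"] | maskset.masks["pS129"]
             | maskset.masks["Cterm"])
    if not union.any():
        return []
    labels = measure.label(union, connectivity=1 if connectivity == 4 else 2)
    n_comp = labels.max()
    areas = np.bincount(labels.ravel(), minlength=n_comp + 1)
    centroids = ndimage.center_of_mass(union, labels, np.arange(1, n_comp + 1))
    per_channel = {}
    for epi in EPITOPES:
        per_channel[epi] = np.bincount(
            labels.ravel(), weights=maskset.masks[epi].ravel().astype(float),
            minlength=n_comp + 1,
        )
    profiles = []
    for cid in range(1, n_comp + 1):
        area = int(areas[cid])
        cov = {epi: float(per_channel[epi][cid] / area) for epi in EPITOPES}
        label = "mixed"
        for epi in EPITOPES:
            others = [cov[o] for o in EPITOPES if o != epi]
            if cov[epi] >= 1.0 - epsilon and all(v <= epsilon for v in others):
                label = f"{_LETTER[epi]}_exclusive"
                break
        profiles.append(AggregateProfile(
            component_id=cid, area_px=area,
            centroid=tuple(float(v) for v in centroids[cid - 1]),
            coverage=cov, exclusivity=label,
        ))
    return profiles
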