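"""Reading and writing the formats the pipeline touches.

Images travel as plain multi-page TIFF, one page per epitope channel, with a
small JSON blob in each page description carrying the channel label, the pixel
size and the section metadata.  Binary masks are single-channel TIFF stored
0/255.  Tabular outputs are CSV written with a fixed row order and full float
precision so that re-running a pipeline with the same seed yields
byte-identical files.

Conventions used everywhere in the package: row-major rasters, 0-based pixel
indices, channel order (Nterm, pS129, Cterm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

#: Canonical epitope channel order: N-terminus (aa 34-45), phospho-Ser129,
#: C-terminus (aa 118-123) antibody channels.
EPITOPES: tuple[str, str, str] = ("Nterm", "pS129", "Cterm")

#: Disease groups carried as metadata.
GROUPS: tuple[str, str, str] = ("PD", "MSA", "control")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass
class SectionMetadata:
    """Identity of one tissue section: case, disease group, brain region."""

    case_id: str = ""
    group: str = "control"
    region: str = ""
    tags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "group": self.group,
            "region": self.region,
            "tags": dict(self.tags),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SectionMetadata":
        return cls(
            case_id=str(d.get("case_id", "")),
            group=str(d.get("group", "control")),
            region=str(d.get("region", "")),
            tags=dict(d.get("tags", {})),
        )


@dataclass
class MultiplexSection:
    """Co-registered three-channel immunofluorescence section.

    Parameters
    ----------
    channels
        Mapping from epitope label (``Nterm``, ``pS129``, ``Cterm``) to a 2-D
        unsigned-integer intensity raster.  All rasters must share one shape.
    pixel_size_um
        Physical pixel edge length in micrometres; must be positive.
    metadata
        Case / group / region identity.
    tissue_mask
        Optional precomputed boolean tissue mask (same shape as the channels).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    metadata: SectionMetadata = field(default_factory=SectionMetadata)
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if set(self.channels) != set(EPITOPES):
            raise ValueError(
                f"section needs exactly the channels {EPITOPES}, "
                f"got {tuple(self.channels)}"
            )
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if arr.dtype.kind != "u":
                raise ValueError(
                    f"channel {name!r} has dtype {arr.dtype}; expected unsigned int"
                )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.tissue_mask is not None:
            if self.tissue_mask.shape != self.shape:
                raise ValueError("tissue_mask shape differs from channels")
            self.tissue_mask = self.tissue_mask.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


# ---------------------------------------------------------------------------
# TIFF section I/O
# ---------------------------------------------------------------------------

def write_section(section: MultiplexSection, path: str | Path) -> Path:
    """Write a section as a 3-page TIFF, one page per channel in canonical order.

    Each page description holds JSON with the channel label, pixel size and
    the section metadata, so a file round-trips without sidecars.
    """
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name in EPITOPES:
            desc = json.dumps(
                {
                    "channel": name,
                    "pixel_size_um": round(float(section.pixel_size_um), 6),
                    "metadata": section.metadata.to_dict(),
                },
                sort_keys=True,
            )
            tif.write(section.channels[name], description=desc, contiguous=False)
    return path


def read_section(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    metadata: SectionMetadata | None = None,
) -> MultiplexSection:
    """Read a multi-page TIFF into a :class:`MultiplexSection`.

    Parameters
    ----------
    channel_map
        Epitope label -> page index.  Defaults to pages 0,1,2 in canonical
        order.  Every referenced page must exist.
    metadata
        Overrides any metadata embedded in the file.

    Raises
    ------
    FormatError
        Missing page, shape mismatch across pages, or a page whose sample
        format is not unsigned integer (float / RGB data is rejected).
    """
    path = Path(path)
    if channel_map is None:
        channel_map = {name: i for i, name in enumerate(EPITOPES)}
    missing = set(EPITOPES) - set(channel_map)
    if missing:
        raise FormatError(f"channel_map does not cover epitopes: {sorted(missing)}")

    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        channels: dict[str, np.ndarray] = {}
        embedded: dict | None = None
        pixel_size = None
        for name, idx in channel_map.items():
            if not 0 <= idx < n_pages:
                raise FormatError(
                    f"channel {name!r} maps to page {idx} but file has {n_pages} pages"
                )
            page = tif.pages[idx]
            arr = page.asarray()
            if arr.ndim != 2 or arr.dtype.kind != "u":
                raise FormatError(
                    f"page {idx} has unsupported sample format "
                    f"(dtype {arr.dtype}, ndim {arr.ndim}); expected 2-D unsigned int"
                )
            channels[name] = arr
            if page.description:
                try:
                    info = json.loads(page.description)
                except json.JSONDecodeError:
                    info = None
                if isinstance(info, dict):
                    pixel_size = info.get("pixel_size_um", pixel_size)
                    embedded = info.get("metadata", embedded)

    shapes = {a.shape for a in channels.values()}
    if len(shapes) != 1:
        raise FormatError(f"pages differ in shape: {shapes}")

    if metadata is None:
        metadata = (
            SectionMetadata.from_dict(embedded) if embedded else SectionMetadata()
        )
    return MultiplexSection(
        channels=channels,
        pixel_size_um=float(pixel_size) if pixel_size else 1.0,
        metadata=metadata,
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as single-channel TIFF, foreground = 255."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 mask TIFF back to boolean."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise FormatError(f"mask file {path} is not single-channel 2-D")
    return arr > 0


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------

#: Venn compartment labels in fixed output order.
COMPARTMENTS: tuple[str, ...] = (
    "N_only", "P_only", "C_only", "NP_only", "NC_only", "PC_only", "NPC",
)


def quant_record_rows(record) -> list[tuple[str, str, str, str, float]]:
    """Flatten one QuantRecord into (case, group, region, measure, value) rows.

    Schema: 1 pathology-load row + 3 total + 3 unique + 7 compartment-area
    rows = 14 rows per record, in fixed order.
    """
    md = record.metadata
    rows = [(md.case_id, md.group, md.region, "pathology_load_pct",
             float(record.pathology_load_pct))]
    for epi in EPITOPES:
        rows.append((md.case_id, md.group, md.region,
                     f"total_pct_{epi}", float(record.total_pct[epi])))
    for epi in EPITOPES:
        rows.append((md.case_id, md.group, md.region,
                     f"unique_pct_{epi}", float(record.unique_pct[epi])))
    for comp in COMPARTMENTS:
        rows.append((md.case_id, md.group, md.region,
                     f"area_px_{comp}", float(getattr(record.venn, comp))))
    return rows


def write_quant_table(records: Sequence, path: str | Path) -> Path:
    """Write QuantRecords as long-format CSV.

    One row per case x region x measure; rows sorted by (case, region) with
    the 14 measures in schema order inside each section; floats at repr
    precision so values survive a parse round-trip to >= 12 significant
    digits.  Identical input yields a byte-identical file.
    """
    if not records:
        raise ValueError("no records to write")
    all_rows: list[tuple[str, str, str, str, float]] = []
    for rec in sorted(records, key=lambda r: (r.metadata.case_id, r.metadata.region)):
        all_rows.extend(quant_record_rows(rec))
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("case_id,group,region,measure,value\n")
        for case, group, region, measure, value in all_rows:
            fh.write(f"{case},{group},{region},{measure},{value!r}\n")
    return path


def read_quant_table(path: str | Path):
    """Read a quant CSV back as a pandas DataFrame (long format)."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"case_id": str, "group": str, "region": str})
    expected = {"case_id", "group", "region", "measure", "value"}
    if not expected.issubset(df.columns):
        raise FormatError(f"quant table missing columns {expected - set(df.columns)}")
    return df
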