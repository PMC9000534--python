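"""Reading and writing MSP peak lists and the sample manifest.

The input is the text MSP export of a GC-MS deconvolution tool (one record
per detected compound): ``KEY: value`` header lines, a ``Num Peaks: n`` line,
then n whitespace-separated ``m/z intensity`` ion lines, records separated by
blank lines.  Retention time is read from ``RETENTIONTIME``/``RT``/
``RETENTION_TIME`` (case-insensitive, first match wins; export dialects
differ across versions).  The chromatographic peak area is taken from the
``INTENSITY`` header; if absent, the raw base-peak intensity is used and a
warning is logged — deconvolution exports do not consistently name the area
field.

Malformed records (ion-count mismatch, missing RT, no retained ions) are
skipped with a logged warning rather than aborting the run: a single bad
record in a 300-compound peak list must not kill a batch.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .spectra import Spectrum, normalize_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PeakRecord",
    "SampleManifest",
    "ManifestEntry",
    "parse_msp",
    "read_manifest",
    "write_msp",
    "DEFAULT_MIN_RT",
    "DEFAULT_MAX_RT",
    "DEFAULT_MIN_MZ",
    "DEFAULT_MAX_MZ",
]

# Default acquisition windows for small volatiles: RT 1-35 min, m/z 30-300.
DEFAULT_MIN_RT = 1.0
DEFAULT_MAX_RT = 35.0
DEFAULT_MIN_MZ = 30.0
DEFAULT_MAX_MZ = 300.0

_RT_KEYS = ("retentiontime", "rt", "retention_time")


@dataclass(frozen=True)
class PeakRecord:
    """One deconvoluted compound in one sample."""

    name: str
    rt: float  # minutes
    area: float  # chromatographic peak area, arbitrary counts
    spectrum: Spectrum

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"retention time must be positive, got {self.rt}")
        if self.area < 0:
            raise ValueError(f"peak area must be non-negative, got {self.area}")

    @property
    def base_peak_mz(self) -> float:
        return self.spectrum.base_peak_mz


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    sample_id: str
    group: str


@dataclass(frozen=True)
class SampleManifest:
    """Ordered sample -> group assignment with one group designated blank."""

    entries: tuple[ManifestEntry, ...]
    blank_group: str

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for entry in self.entries:
            seen.setdefault(entry.group, None)
        return tuple(seen)

    def entries_for(self, group: str) -> tuple[ManifestEntry, ...]:
        return tuple(e for e in self.entries if e.group == group)


def parse_msp(
    path: str | Path,
    min_rt: float = DEFAULT_MIN_RT,
    max_rt: float = DEFAULT_MAX_RT,
    min_mz: float = DEFAULT_MIN_MZ,
    max_mz: float = DEFAULT_MAX_MZ,
) -> list[PeakRecord]:
    """Parse an MSP peak list into records sorted by ascending RT.

    Records with RT outside [min_rt, max_rt] are dropped; ions outside
    [min_mz, max_mz] or with non-positive intensity are dropped before the
    top-7 truncation.  An empty file yields an empty list.
    """
    path = Path(path)
    records: list[PeakRecord] = []
    for block_no, block in enumerate(_record_blocks(path)):
        record = _parse_record(block, path, block_no, min_rt, max_rt, min_mz, max_mz)
        if record is not None:
            records.append(record)
    records.sort(key=lambda r: r.rt)
    return records


def _record_blocks(path: Path) -> Iterable[list[str]]:
    block: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n").rstrip("\r")
            if line.strip():
                block.append(line)
            elif block:
                yield block
                block = []
    if block:
        yield block


def _parse_record(
    block: list[str],
    path: Path,
    block_no: int,
    min_rt: float,
    max_rt: float,
    min_mz: float,
    max_mz: float,
) -> PeakRecord | None:
    headers: dict[str, str] = {}
    ions: list[tuple[float, float]] = []
    declared: int | None = None
    i = 0
    while i < len(block):
        line = block[i]
        if ":" in line and declared is None:
            key, _, value = line.partition(":")
            key_norm = key.strip().lower()
            headers.setdefault(key_norm, value.strip())
            if key_norm == "num peaks":
                try:
                    declared = int(value.strip())
                except ValueError:
                    logger.warning("%s record %d: bad Num Peaks value; skipped", path, block_no)
                    return None
        elif declared is not None:
            parts = line.split()
            if len(parts) < 2:
                logger.warning("%s record %d: malformed ion line; skipped", path, block_no)
                return None
            try:
                ions.append((float(parts[0]), float(parts[1])))
            except ValueError:
                logger.warning("%s record %d: malformed ion line; skipped", path, block_no)
                return None
        i += 1

    if declared is None or declared != len(ions):
        logger.warning(
            "%s record %d: ion count mismatch (declared %s, found %d); skipped",
            path, block_no, declared, len(ions),
        )
        return None

    rt = None
    for key in _RT_KEYS:
        if key in headers:
            try:
                rt = float(headers[key])
            except ValueError:
                pass
            break
    if rt is None:
        logger.warning("%s record %d: missing retention time; skipped", path, block_no)
        return None
    if not (min_rt <= rt <= max_rt):
        return None

    kept = [(mz, inten) for mz, inten in ions if min_mz <= mz <= max_mz and inten > 0]
    if not kept:
        logger.warning("%s record %d: no ions inside the m/z window; skipped", path, block_no)
        return None
    spectrum = normalize_spectrum(kept)

    if "intensity" in headers:
        try:
            area = float(headers["intensity"])
        except ValueError:
            logger.warning("%s record %d: bad INTENSITY value; skipped", path, block_no)
            return None
    else:
        area = max(inten for _, inten in kept)
        logger.warning(
            "%s record %d: no INTENSITY header; using raw base-peak intensity as area",
            path, block_no,
        )
    name = headers.get("name", f"record_{block_no}")
    return PeakRecord(name=name, rt=rt, area=area, spectrum=spectrum)


def write_msp(records: Sequence[PeakRecord], path: str | Path) -> None:
    """Write records in MSP text form readable back by :func:`parse_msp`.

    RT is written to 3 decimals, m/z to 4 decimals and intensity to 1 decimal;
    relative intensities are written on a 0-1000 scale so one decimal place
    preserves them to ~1e-4 of the base peak on round trip.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        for record in records:
            handle.write(f"NAME: {record.name}\n")
            handle.write(f"RETENTIONTIME: {record.rt:.3f}\n")
            handle.write(f"INTENSITY: {record.area:.1f}\n")
            handle.write(f"Num Peaks: {len(record.spectrum)}\n")
            for mz, rel in record.spectrum.ions:
                handle.write(f"{mz:.4f}\t{rel * 1000.0:.1f}\n")
            handle.write("\n")


def read_manifest(path: str | Path, blank_group: str = "blank") -> SampleManifest:
    """Read the sample list (columns ``file``, ``sample_id``, ``group``).

    Tab- or comma-separated with a header row; file paths are resolved
    relative to the manifest's directory.  Duplicate sample ids or a missing
    blank group are hard errors.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"manifest {path} is empty")
    delimiter = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=delimiter)
    required = {"file", "sample_id", "group"}
    fields = {f.strip().lower() for f in reader.fieldnames or ()}
    if not required <= fields:
        raise ValueError(f"manifest {path} must have columns file, sample_id, group")

    entries: list[ManifestEntry] = []
    seen_ids: set[str] = set()
    for row in reader:
        row = {k.strip().lower(): (v or "").strip() for k, v in row.items()}
        sample_id = row["sample_id"]
        if sample_id in seen_ids:
            raise ValueError(f"duplicate sample_id {sample_id!r} in manifest {path}")
        seen_ids.add(sample_id)
        file_path = Path(row["file"])
        if not file_path.is_absolute():
            file_path = path.parent / file_path
        entries.append(ManifestEntry(path=file_path, sample_id=sample_id, group=row["group"]))

    if not entries:
        raise ValueError(f"manifest {path} has no samples")
    groups = {e.group for e in entries}
    if blank_group not in groups:
        raise ValueError(f"blank group {blank_group!r} not present in manifest {path}")
    missing = [str(e.path) for e in entries if not e.path.exists()]
    if missing:
        raise FileNotFoundError(f"manifest {path} references missing files: {missing}")
    return SampleManifest(entries=tuple(entries), blank_group=blank_group)
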