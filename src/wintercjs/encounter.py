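"""Encounter-history data model, I/O and data-selection rules.

The study design: Eurasian spoonbills colour-ringed as chicks at a single
Mediterranean breeding colony are first individually identified at a
wintering site somewhere along the East Atlantic (EAF) or Central European
(CEF) flyway, or at the colony region itself (residents).  That first winter
sighting opens the encounter history; all subsequent occasions are annual
breeding-season resighting occasions at the colony.

Occasion convention
-------------------
A single occasion axis of calendar years (2008..2020 in the study) carries
both kinds of occasions: the entry winter spanning years ``y``/``y+1`` sits
in slot ``y`` and the breeding season of year ``j`` sits in slot ``j``.  The
interval from an individual's entry slot to the next breeding slot is half a
year; every later interval is a full year.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FLYWAYS",
    "DISTANCES",
    "REGION_LABELS",
    "DEFAULT_COUNTRY_REGIONS",
    "WinteringRegion",
    "OccasionAxis",
    "Resighting",
    "EncounterHistory",
    "Dataset",
    "RawRecord",
    "Exclusion",
    "MArray",
    "winter_of",
    "assign_wintering_region",
    "apply_exclusions",
    "build_marray",
    "read_histories",
    "write_histories",
]

FLYWAYS = ("EAF", "CEF", "RES")
DISTANCES = ("LD", "SD", "RES")
REGION_LABELS = ("EAF LD", "EAF SD", "CEF LD", "CEF SD", "RES")

#: Country -> region label used to classify winter resightings.  ``None``
#: marks a country outside the recognised wintering areas (such records lead
#: to exclusion).  West Algeria belongs with the EAF long-distance birds:
#: tracked individuals use the East Atlantic flyway through West Algeria.
DEFAULT_COUNTRY_REGIONS: dict[str, str | None] = {
    "Cape Verde": "EAF LD",
    "Gambia": "EAF LD",
    "Morocco": "EAF LD",
    "Mauritania": "EAF LD",
    "Senegal": "EAF LD",
    "West Algeria": "EAF LD",
    "Portugal": "EAF SD",
    "Spain": "EAF SD",
    "Southwest France": "EAF SD",
    "East Algeria": "CEF LD",
    "Tunisia": "CEF LD",
    "Italy": "CEF SD",
    "France": "RES",
    "South Sudan": None,
}

#: Months that qualify a resighting as a winter record.  Long-distance birds
#: use the broad October-February window; short-distance and resident birds
#: use November-January to avoid counting autumn/spring stopovers.
WINTER_MONTHS_LD = (10, 11, 12, 1, 2)
WINTER_MONTHS_SD = (11, 12, 1)

#: Breeding-season months at the colony (spring/summer).
BREEDING_MONTHS = (3, 4, 5, 6, 7)


class ConfigurationError(ValueError):
    """Raised for unknown countries or inconsistent lookup tables."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class WinteringRegion:
    """One of the five flyway x migration-distance wintering strategies."""

    flyway: str
    distance: str

    def __post_init__(self) -> None:
        if self.flyway not in FLYWAYS or self.distance not in DISTANCES:
            raise ValueError(f"unknown flyway/distance: {self.flyway}/{self.distance}")
        if (self.flyway == "RES") != (self.distance == "RES"):
            raise ValueError("RES is resident on both axes or on neither")
        if self.label not in REGION_LABELS:
            raise ValueError(f"invalid region label {self.label!r}")

    @property
    def label(self) -> str:
        return "RES" if self.flyway == "RES" else f"{self.flyway} {self.distance}"

    @classmethod
    def from_label(cls, label: str) -> "WinteringRegion":
        label = label.strip()
        if label == "RES":
            return cls("RES", "RES")
        try:
            flyway, distance = label.split()
            return cls(flyway, distance)
        except ValueError as exc:
            raise ValueError(f"unknown region label {label!r}") from exc


@dataclass(frozen=True)
class OccasionAxis:
    """Shared axis of breeding occasions with entry winters interleaved.

    ``breeding_years`` are the annual breeding occasions; an entry winter
    ``y``/``y+1`` is valid for every ``y`` from the first breeding year to
    the penultimate one, and precedes breeding occasion ``y+1`` by half a
    year.
    """

    breeding_years: tuple[int, ...] = tuple(range(2008, 2021))

    def __post_init__(self) -> None:
        ys = self.breeding_years
        if len(ys) < 2 or any(b - a != 1 for a, b in zip(ys, ys[1:])):
            raise ValueError("breeding occasions must increase by exactly 1")

    @property
    def entry_winters(self) -> tuple[int, ...]:
        return self.breeding_years[:-1]

    @property
    def n_occasions(self) -> int:
        return len(self.breeding_years)

    def first_occasion(self, entry_winter: int) -> int:
        """Breeding year of the first post-entry occasion."""
        if entry_winter not in self.entry_winters:
            raise ValueError(f"entry winter {entry_winter} outside axis")
        return entry_winter + 1

    def interval_lengths(self, entry_winter: int) -> tuple[float, ...]:
        """Half a year to the first breeding occasion, a year thereafter."""
        n_after = self.breeding_years[-1] - self.first_occasion(entry_winter)
        return (0.5,) + (1.0,) * n_after


@dataclass(frozen=True)
class Resighting:
    individual_id: str
    year: int
    month: int
    country: str
    site: str = ""
    latitude: float = float("nan")
    at_colony: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month {self.month} outside 1..12")


def winter_of(year: int, month: int) -> int:
    """Start year of the winter a (year, month) date belongs to.

    October-December belong to the winter starting that year; January and
    February to the winter that started the year before.
    """
    return year if month >= 10 else year - 1


@dataclass(frozen=True)
class Exclusion:
    individual_id: str
    rule: str
    detail: str = ""


@dataclass
class EncounterHistory:
    """One individual's post-entry detection record plus covariates."""

    id: str
    birth_year: int
    entry_winter: int
    detections: np.ndarray
    region: WinteringRegion

    def __post_init__(self) -> None:
        self.detections = np.asarray(self.detections, dtype=np.int8)
        if self.detections.ndim != 1:
            raise ValueError("detections must be a 1-d 0/1 vector")
        if not np.isin(self.detections, (0, 1)).all():
            raise ValueError("detections must contain only 0/1")
        if self.entry_winter < self.birth_year:
            raise ValueError("entry winter precedes birth year")

    @property
    def first_occasion(self) -> int:
        return self.entry_winter + 1

    def detection_years(self) -> tuple[int, ...]:
        return tuple(
            self.first_occasion + i for i, d in enumerate(self.detections) if d
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncounterHistory):
            return NotImplemented
        return (
            self.id == other.id
            and self.birth_year == other.birth_year
            and self.entry_winter == other.entry_winter
            and self.region == other.region
            and np.array_equal(self.detections, other.detections)
        )


@dataclass
class Dataset:
    histories: list[EncounterHistory]
    axis: OccasionAxis
    exclusion_log: list[Exclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h.id for h in self.histories]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in dataset")
        last = self.axis.breeding_years[-1]
        for h in self.histories:
            if h.entry_winter not in self.axis.entry_winters:
                raise ValueError(f"{h.id}: entry winter outside axis")
            if h.first_occasion + len(h.detections) - 1 > last and len(h.detections):
                raise ValueError(f"{h.id}: detections run past axis end")

    def __len__(self) -> int:
        return len(self.histories)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.axis == other.axis
            and self.histories == other.histories
            and self.exclusion_log == other.exclusion_log
        )

    def region_counts(self) -> dict[str, int]:
        out = {lab: 0 for lab in REGION_LABELS}
        for h in self.histories:
            out[h.region.label] += 1
        return out


@dataclass
class RawRecord:
    """Pre-selection record for one ringed individual."""

    id: str
    birth_year: int
    resightings: list[Resighting] = field(default_factory=list)
    ringed_as_adult: bool = False
    recovery: bool = False
    gps_tagged: bool = False
    duplicate_ring: bool = False


# ---------------------------------------------------------------------------
# Wintering-region assignment and exclusion filters
# ---------------------------------------------------------------------------

def _qualifying_winter_sightings(
    resightings: list[Resighting],
    lookup: dict[str, str | None],
) -> tuple[list[tuple[Resighting, str]], bool]:
    """Return (sighting, region-label) pairs that fall in the winter window.

    The window depends on the candidate site's own class: long-distance
    countries use October-February, short-distance/resident ones
    November-January.  Also reports whether any sighting hit an unmatched
    country (present in the lookup but mapping to ``None``).
    """
    qualifying: list[tuple[Resighting, str]] = []
    unmatched = False
    for rs in resightings:
        if rs.country not in lookup:
            raise ConfigurationError(f"unknown country {rs.country!r}")
        label = lookup[rs.country]
        if label is None:
            unmatched = True
            continue
        months = (
            WINTER_MONTHS_LD
            if label.endswith("LD")
            else WINTER_MONTHS_SD
        )
        if rs.month in months:
            qualifying.append((rs, label))
    return qualifying, unmatched


def assign_wintering_region(
    resightings: list[Resighting],
    lookup: dict[str, str | None] | None = None,
) -> WinteringRegion | Exclusion:
    """Classify an individual's wintering strategy from its resightings.

    The southernmost qualifying winter site decides the region (earliest
    date breaks latitude ties).  Individuals whose qualifying sites span two
    flyways, or mix migrant and resident status, are excluded as switchers;
    individuals with no qualifying winter sighting are excluded outright.
    """
    lookup = DEFAULT_COUNTRY_REGIONS if lookup is None else lookup
    ind = resightings[0].individual_id if resightings else "?"
    qualifying, unmatched = _qualifying_winter_sightings(resightings, lookup)
    if not qualifying:
        rule = "unmatched_region" if unmatched else "no_winter"
        return Exclusion(ind, rule)
    flyways = {WinteringRegion.from_label(lab).flyway for _, lab in qualifying}
    if len(flyways) > 1:
        return Exclusion(ind, "switcher", detail=",".join(sorted(flyways)))

    def sort_key(pair: tuple[Resighting, str]) -> tuple[float, int, int]:
        rs, _ = pair
        lat = rs.latitude if np.isfinite(rs.latitude) else 90.0
        return (lat, rs.year, rs.month)

    _, label = min(qualifying, key=sort_key)
    return WinteringRegion.from_label(label)


def entry_winter_of(
    resightings: list[Resighting],
    lookup: dict[str, str | None] | None = None,
) -> int | None:
    """Winter (start year) of the first qualifying winter sighting."""
    lookup = DEFAULT_COUNTRY_REGIONS if lookup is None else lookup
    qualifying, _ = _qualifying_winter_sightings(resightings, lookup)
    if not qualifying:
        return None
    return min(winter_of(rs.year, rs.month) for rs, _ in qualifying)


def apply_exclusions(
    raw_records: list[RawRecord],
    axis: OccasionAxis | None = None,
    lookup: dict[str, str | None] | None = None,
) -> Dataset:
    """Apply the data-selection filters and build an analysis-ready dataset.

    Removes, in order: individuals ringed as adults, recoveries, GPS-tagged
    birds, duplicated rings, flyway/residency switchers, birds never seen in
    winter (or only at unrecognised sites).  Breeding detections are
    collapsed to one binary observation per individual per year.  Every
    removal is logged with its rule.
    """
    axis = OccasionAxis() if axis is None else axis
    histories: list[EncounterHistory] = []
    log: list[Exclusion] = []
    flag_rules = (
        ("ringed_as_adult", "ringed_as_adult"),
        ("recovery", "recovery"),
        ("gps_tagged", "gps_tagged"),
        ("duplicate_ring", "duplicate_ring"),
    )
    for rec in raw_records:
        flagged = False
        for attr, rule in flag_rules:
            if getattr(rec, attr):
                log.append(Exclusion(rec.id, rule))
                flagged = True
                break
        if flagged:
            continue
        region = assign_wintering_region(rec.resightings, lookup)
        if isinstance(region, Exclusion):
            log.append(replace(region, individual_id=rec.id))
            continue
        entry = entry_winter_of(rec.resightings, lookup)
        assert entry is not None
        if entry not in axis.entry_winters:
            log.append(Exclusion(rec.id, "no_occasions", f"entry winter {entry}"))
            continue
        first = axis.first_occasion(entry)
        last = axis.breeding_years[-1]
        det = np.zeros(last - first + 1, dtype=np.int8)
        for rs in rec.resightings:
            if rs.at_colony and rs.month in BREEDING_MONTHS and first <= rs.year <= last:
                det[rs.year - first] = 1  # one observation per year
        histories.append(
            EncounterHistory(rec.id, rec.birth_year, entry, det, region)
        )
    return Dataset(histories, axis, log)


# ---------------------------------------------------------------------------
# m-array sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class MArray:
    """Release/first-reencounter counts by group, stratified new vs old.

    ``releases[g, s, i]`` counts releases of stratum ``s`` (0 = newly marked,
    i.e. the winter-entry release; 1 = re-release after a breeding-season
    detection) at occasion slot ``i``; ``m[g, s, i, j]`` counts those first
    reencountered at slot ``j > i``.  The never-seen-again column completes
    each row.
    """

    occasions: tuple[int, ...]
    groups: tuple[str, ...]
    releases: np.ndarray  # (G, 2, T)
    m: np.ndarray  # (G, 2, T, T)

    @property
    def never(self) -> np.ndarray:
        return self.releases - self.m.sum(axis=-1)

    def pooled(self) -> "MArray":
        """Collapse all groups into one."""
        return MArray(
            self.occasions,
            ("all",),
            self.releases.sum(axis=0, keepdims=True),
            self.m.sum(axis=0, keepdims=True),
        )


def build_marray(
    dataset: Dataset,
    grouping: dict[str, str] | None = None,
) -> MArray:
    """Sufficient-statistic m-array for the dataset.

    ``grouping`` maps individual id to a group name; the default groups by
    the five wintering regions.  Row sums (first-reencounter counts plus the
    never-seen column) equal the releases by construction.
    """
    years = dataset.axis.breeding_years
    T = len(years)
    y0 = years[0]
    if grouping is None:
        grouping = {h.id: h.region.label for h in dataset.histories}
        group_names = [g for g in REGION_LABELS
                       if any(v == g for v in grouping.values())] or list(REGION_LABELS)
    else:
        group_names = sorted(set(grouping.values()))
    gidx = {g: k for k, g in enumerate(group_names)}
    G = len(group_names)
    releases = np.zeros((G, 2, T), dtype=np.int64)
    m = np.zeros((G, 2, T, T), dtype=np.int64)
    for h in dataset.histories:
        g = gidx[grouping[h.id]]
        slots = [h.entry_winter - y0] + [y - y0 for y in h.detection_years()]
        for k, i in enumerate(slots):
            s = 0 if k == 0 else 1
            releases[g, s, i] += 1
            if k + 1 < len(slots):
                m[g, s, i, slots[k + 1]] += 1
    return MArray(tuple(years), tuple(group_names), releases, m)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("id", "birth_year", "entry_winter", "history", "region")


def write_histories(dataset: Dataset, path: str, dialect: str = "csv") -> None:
    """Write a dataset in the canonical CSV dialect or as a MARK-style .inp.

    CSV carries an axis comment line so files round-trip exactly.  The .inp
    dialect encodes the full-axis history (first 1 = winter entry) with the
    five region dummy columns, plus a sidecar ``<path>.sidecar.tsv`` holding
    id and birth year per row (the .inp line itself cannot carry them).
    """
    ys = dataset.axis.breeding_years
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# axis: {ys[0]}-{ys[-1]}\n")
            w = csv.writer(fh)
            w.writerow(_CSV_FIELDS)
            for h in dataset.histories:
                w.writerow([
                    h.id,
                    h.birth_year,
                    f"{h.entry_winter}w",
                    "".join(str(int(d)) for d in h.detections),
                    h.region.label,
                ])
    elif dialect == "mark_inp":
        y0 = ys[0]
        with open(path, "w") as fh, open(path + ".sidecar.tsv", "w") as sc:
            sc.write("id\tbirth_year\n")
            for h in dataset.histories:
                full = np.zeros(len(ys), dtype=np.int8)
                full[h.entry_winter - y0] = 1
                for y in h.detection_years():
                    full[y - y0] = 1
                dummies = [
                    "1" if h.region.label == lab else "0" for lab in REGION_LABELS
                ]
                fh.write("".join(map(str, full)) + " " + " ".join(dummies) + ";\n")
                sc.write(f"{h.id}\t{h.birth_year}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _parse_axis_comment(line: str) -> OccasionAxis | None:
    line = line.strip()
    if line.startswith("#") and "axis:" in line:
        span = line.split("axis:")[1].strip()
        a, b = span.split("-")
        return OccasionAxis(tuple(range(int(a), int(b) + 1)))
    return None


def read_histories(
    path: str,
    dialect: str = "csv",
    axis: OccasionAxis | None = None,
) -> Dataset:
    """Read encounter histories written by :func:`write_histories`.

    For CSV the axis comes from the leading ``# axis:`` comment, the ``axis``
    argument, or (last resort) the span covered by the rows.  For .inp the
    line length fixes the axis width; pass ``axis`` to anchor the first year
    (default 2008).
    """
    if dialect == "csv":
        return _read_csv(path, axis)
    if dialect == "mark_inp":
        return _read_inp(path, axis)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(path: str, axis: OccasionAxis | None) -> Dataset:
    with open(path, newline="") as fh:
        text = fh.read()
    lines = text.splitlines()
    rows: list[tuple[str, int, int, str, WinteringRegion]] = []
    header_seen = False
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            found = _parse_axis_comment(line)
            if found is not None and axis is None:
                axis = found
            continue
        parts = next(csv.reader(io.StringIO(line)))
        if not header_seen:
            if tuple(p.strip() for p in parts) != _CSV_FIELDS:
                raise ParseError(f"line {lineno}: expected header {_CSV_FIELDS}")
            header_seen = True
            continue
        if len(parts) != len(_CSV_FIELDS):
            raise ParseError(f"line {lineno}: expected {len(_CSV_FIELDS)} fields")
        ident, by, ew, hist, reg = (p.strip() for p in parts)
        try:
            birth = int(by)
            entry = int(ew.rstrip("wW"))
            if hist and set(hist) - {"0", "1"}:
                raise ValueError("history must be 0/1")
            region = WinteringRegion.from_label(reg)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        rows.append((ident, birth, entry, hist, region))
    if axis is None:
        if not rows:
            raise ParseError("empty file and no axis given")
        lo = min(r[2] for r in rows)
        hi = max(r[2] + len(r[3]) for r in rows)
        axis = OccasionAxis(tuple(range(lo, hi + 1)))
    histories = [
        EncounterHistory(ident, birth, entry,
                         np.fromiter(map(int, hist), dtype=np.int8,
                                     count=len(hist)),
                         region)
        for ident, birth, entry, hist, region in rows
    ]
    return Dataset(histories, axis)


def _read_inp(path: str, axis: OccasionAxis | None) -> Dataset:
    sidecar = path + ".sidecar.tsv"
    meta: list[tuple[str, int]] = []
    try:
        with open(sidecar) as fh:
            next(fh)
            for line in fh:
                ident, by = line.rstrip("\n").split("\t")
                meta.append((ident, int(by)))
    except FileNotFoundError:
        meta = []
    histories: list[EncounterHistory] = []
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    for k, line in enumerate(lines):
        body = line.strip().rstrip(";").strip()
        parts = body.split()
        if len(parts) != 1 + len(REGION_LABELS):
            raise ParseError(f"line {k + 1}: expected history + 5 group columns")
        hist, dummies = parts[0], parts[1:]
        if set(hist) - {"0", "1"} or dummies.count("1") != 1:
            raise ParseError(f"line {k + 1}: malformed history or group columns")
        region = WinteringRegion.from_label(REGION_LABELS[dummies.index("1")])
        if axis is None:
            axis = OccasionAxis(tuple(range(2008, 2008 + len(hist))))
        if len(hist) != axis.n_occasions:
            raise ParseError(f"line {k + 1}: history length != axis width")
        y0 = axis.breeding_years[0]
        ones = [i for i, c in enumerate(hist) if c == "1"]
        entry_slot = ones[0]
        entry = y0 + entry_slot
        det = np.zeros(axis.n_occasions - entry_slot - 1, dtype=np.int8)
        for i in ones[1:]:
            det[i - entry_slot - 1] = 1
        ident, birth = meta[k] if k < len(meta) else (f"inp{k:05d}", entry)
        histories.append(EncounterHistory(ident, birth, entry, det, region))
    if axis is None:
        raise ParseError("empty .inp file and no axis given")
    return Dataset(histories, axis)
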