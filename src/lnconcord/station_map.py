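"""Nodal station registry and distance-band classification.

Lymph-node stations are grouped, following the JSCCR-style map used in
colorectal staging, into three bands by distance from the primary tumor:
``locoregional`` (within 5 cm), ``intermediate`` (5-10 cm, alongside the
great vessels) and ``central`` (beyond 10 cm, at the origin of the great
vessels).  A :class:`StationRegistry` maps short alphanumeric station codes
(e.g. ``"241"``, ``"251"``) to a band, an anatomic label and the tumor
sites the station is relevant for.

The shipped default registry is illustrative: it guarantees the two codes
named in colorectal practice for sigmoid and superior-rectum tumors (241,
251) and at least one station per band for every tumor site, but it is not
the complete official JSCCR atlas.  Supply a registry TSV for real work.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from .errors import DomainError, FormatError, VocabularyError


class DistanceBand(enum.IntEnum):
    """Band of a nodal station by distance from the primary tumor.

    Integer ordering encodes increasing distance, so bands compare with
    ``<`` in the order locoregional < intermediate < central.
    """

    locoregional = 0
    intermediate = 1
    central = 2

    def __str__(self) -> str:  # serialise as the plain label
        return self.name


class TumorSite(enum.Enum):
    """The eight primary-tumor localizations used throughout the cohort."""

    cecum = "cecum"
    ascending = "ascending"
    transverse = "transverse"
    descending = "descending"
    sigmoid = "sigmoid"
    superior_rectum = "superior_rectum"
    middle_rectum = "middle_rectum"
    inferior_rectum = "inferior_rectum"

    def __str__(self) -> str:
        return self.value


#: Locoregional band is closed at 5 cm, intermediate half-open at 10 cm.
#: "within 5 cm" is read inclusively; this is the single place the
#: convention lives, so flipping it changes every caller consistently.
LOCOREGIONAL_MAX_CM = 5.0
INTERMEDIATE_MAX_CM = 10.0


def classify_distance(distance_cm: float) -> DistanceBand:
    """Classify a tumor-to-station distance (cm) into its band.

    [0, 5] -> locoregional, (5, 10] -> intermediate, (10, inf) -> central.

    Raises
    ------
    DomainError
        If the distance is negative, NaN or infinite.
    """
    if not isinstance(distance_cm, (int, float)) or isinstance(distance_cm, bool):
        raise DomainError(f"distance must be a real number, got {distance_cm!r}")
    if not math.isfinite(distance_cm) or distance_cm < 0:
        raise DomainError(
            f"distance must be finite and non-negative, got {distance_cm!r}"
        )
    if distance_cm <= LOCOREGIONAL_MAX_CM:
        return DistanceBand.locoregional
    if distance_cm <= INTERMEDIATE_MAX_CM:
        return DistanceBand.intermediate
    return DistanceBand.central


def parse_band(label: str) -> DistanceBand:
    """Parse a band label (case-insensitive); raise VocabularyError otherwise."""
    try:
        return DistanceBand[str(label).strip().lower()]
    except KeyError:
        allowed = ", ".join(b.name for b in DistanceBand)
        raise VocabularyError(
            f"unknown distance band {label!r}; allowed: {allowed}"
        ) from None


def parse_site(label: str) -> TumorSite:
    """Parse a tumor-site label (case-insensitive); raise VocabularyError otherwise."""
    try:
        return TumorSite(str(label).strip().lower())
    except ValueError:
        allowed = ", ".join(s.value for s in TumorSite)
        raise VocabularyError(
            f"unknown tumor site {label!r}; allowed: {allowed}"
        ) from None


@dataclass(frozen=True)
class Station:
    """One nodal station: code, distance band, anatomic label, applicable sites.

    Codes are strings, never integers, to preserve leading characters in
    other coding systems.
    """

    code: str
    band: DistanceBand
    anatomic_label: str = ""
    applicable_sites: frozenset[TumorSite] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.code or not str(self.code).strip():
            raise FormatError("station code must be a non-empty string")
        object.__setattr__(self, "code", str(self.code).strip())
        object.__setattr__(self, "applicable_sites", frozenset(self.applicable_sites))


@dataclass(frozen=True)
class StationRegistry:
    """Validated collection of stations with injective code lookup."""

    stations: tuple[Station, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: dict[str, Station] = {}
        for st in self.stations:
            if st.code in seen:
                raise FormatError(f"duplicate station code {st.code!r} in registry")
            seen[st.code] = st
        object.__setattr__(self, "stations", tuple(self.stations))
        object.__setattr__(self, "_by_code", seen)

    def __len__(self) -> int:
        return len(self.stations)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code  # type: ignore[attr-defined]

    def get(self, code: str) -> Station:
        try:
            return self._by_code[code]  # type: ignore[attr-defined]
        except KeyError:
            raise DomainError(f"station code {code!r} not in registry") from None

    def codes(self) -> list[str]:
        return [st.code for st in self.stations]


def stations_for_site(registry: StationRegistry, site: Union[TumorSite, str]) -> list[Station]:
    """All stations applicable to *site*, ordered band-then-code.

    Raises DomainError if the registry has no station for the site.
    """
    site = parse_site(site) if isinstance(site, str) else site
    if not isinstance(site, TumorSite):
        raise VocabularyError(f"not a tumor site: {site!r}")
    hits = [st for st in registry.stations if site in st.applicable_sites]
    if not hits:
        raise DomainError(f"registry has no station applicable to site {site}")
    return sorted(hits, key=lambda st: (int(st.band), st.code))


_COLUMNS = ("code", "band", "anatomic_label", "applicable_sites")


def load_registry(path: Union[str, Path], version: str | None = None) -> StationRegistry:
    """Load a registry from TSV.

    Expected header: ``code<TAB>band<TAB>anatomic_label<TAB>applicable_sites``
    with sites semicolon-separated.  Duplicate codes, unknown bands or sites
    and missing columns raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty registry file")
    header = tuple(h.strip() for h in lines[0].split("\t"))
    if header != _COLUMNS:
        raise FormatError(
            f"{path}: line 1: expected columns {list(_COLUMNS)}, got {list(header)}"
        )
    stations: list[Station] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != len(_COLUMNS):
            raise FormatError(
                f"{path}: line {lineno}: expected {len(_COLUMNS)} tab-separated "
                f"fields, got {len(parts)}"
            )
        code, band_label, anatomic, sites_field = (p.strip() for p in parts)
        try:
            band = parse_band(band_label)
            sites = frozenset(
                parse_site(s) for s in sites_field.split(";") if s.strip()
            )
        except VocabularyError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        stations.append(Station(code, band, anatomic, sites))
    try:
        registry = StationRegistry(
            tuple(stations), version=version or path.stem
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
    return registry


def write_registry(registry: StationRegistry, path: Union[str, Path]) -> None:
    """Write a registry to the TSV schema read by :func:`load_registry`."""
    path = Path(path)
    rows = ["\t".join(_COLUMNS)]
    for st in registry.stations:
        sites = ";".join(sorted(s.value for s in st.applicable_sites))
        rows.append(f"{st.code}\t{st.band}\t{st.anatomic_label}\t{sites}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def default_registry() -> StationRegistry:
    """The registry shipped with the package (illustrative, not the full atlas)."""
    ref = resources.files("lnconcord.data").joinpath("default_stations.tsv")
    with resources.as_file(ref) as p:
        return load_registry(p, version="lnconcord-default")


def validate_registry_coverage(registry: StationRegistry) -> None:
    """Check every tumor site has at least one station in every band.

    Raises DomainError naming the first uncovered (site, band) pair.
    """
    for site in TumorSite:
        bands = {st.band for st in registry.stations if site in st.applicable_sites}
        for band in DistanceBand:
            if band not in bands:
                raise DomainError(
                    f"registry lacks a {band} station for site {site}"
                )
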