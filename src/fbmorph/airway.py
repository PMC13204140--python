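"""Normative pediatric airway dimensions.

Ships a transcribed reference table of radiographic / ultrasonographic
airway dimensions (glottis, subglottis, cricoid, proximal trachea) plus
age-appropriate endotracheal-tube diameters, for comparison against
object descriptors and for inclusion in narrative prompts. The table is
an anatomical reference for a young child (around 2 years), not a
patient-specific measurement; only the under-4-year radiography block is
available, so no interpolation across ages is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "AirwaySite",
    "AirwayReferenceSet",
    "builtin_reference",
    "load_reference",
    "to_prompt_block",
    "SITES",
]

SITES = ("glottis", "subglottis", "cricoid", "proximal_trachea")
_SEXES = ("male", "female", "unspecified")


@dataclass
class AirwaySite:
    """Normative dimensions at one anatomical level (mm / mm^2)."""

    site: str
    ap_diameter_mm: float | None = None
    ap_sd_mm: float | None = None
    transverse_diameter_mm: float | None = None
    transverse_sd_mm: float | None = None
    cross_section_mm2: float | None = None
    source: str = ""
    sex_specific_diameter_mm: dict | None = None

    def __post_init__(self) -> None:
        for v in (self.ap_diameter_mm, self.transverse_diameter_mm,
                  self.cross_section_mm2):
            if v is not None and v <= 0:
                raise ValueError(f"{self.site}: dimensions must be positive")


@dataclass
class AirwayReferenceSet:
    """Full reference block for one (age, sex) query."""

    age_years: float
    sex: str
    sites: list[AirwaySite] = field(default_factory=list)
    ett_internal_mm: tuple[float, float] = (4.0, 4.5)
    ett_outer_mm: tuple[float, float] = (5.3, 6.0)
    context_notes: list[str] = field(default_factory=list)
    version: str = ""
    approximate: bool = True

    def __post_init__(self) -> None:
        names = [s.site for s in self.sites]
        missing = set(SITES) - set(names)
        if missing:
            raise ValueError(f"reference set missing sites: {sorted(missing)}")
        for lo, hi in (self.ett_internal_mm, self.ett_outer_mm):
            if lo > hi:
                raise ValueError("ETT range must be ordered low <= high")

    def site(self, name: str) -> AirwaySite:
        for s in self.sites:
            if s.site == name:
                return s
        raise KeyError(name)


def _load_builtin() -> dict:
    with resources.files("fbmorph.data").joinpath(
        "airway_reference.json"
    ).open() as fh:
        return json.load(fh)


def _build(table: dict, age_years: float, sex: str) -> AirwayReferenceSet:
    sites = []
    for row in table["sites"]:
        row = dict(row)
        sex_map = row.pop("sex_specific_diameter_mm", None)
        site = AirwaySite(
            site=row["site"],
            ap_diameter_mm=row.get("ap_mean_mm"),
            ap_sd_mm=row.get("ap_sd_mm"),
            transverse_diameter_mm=row.get("transverse_mean_mm"),
            transverse_sd_mm=row.get("transverse_sd_mm"),
            cross_section_mm2=row.get("cross_section_mm2"),
            source=row.get("source", ""),
            sex_specific_diameter_mm=sex_map,
        )
        if sex_map is not None:
            if sex in sex_map:
                site.ap_diameter_mm = float(sex_map[sex])
            else:
                # unspecified sex: the smaller (more conservative) airway
                site.ap_diameter_mm = float(min(sex_map.values()))
        sites.append(site)
    ett = table["ett"]
    return AirwayReferenceSet(
        age_years=age_years,
        sex=sex,
        sites=sites,
        ett_internal_mm=tuple(ett["internal_mm"]),
        ett_outer_mm=tuple(ett["outer_mm"]),
        context_notes=list(table.get("context_notes", [])),
        version=table.get("version", ""),
        approximate=True,
    )


def builtin_reference(age_years: float, sex: str = "unspecified") -> AirwayReferenceSet:
    """Built-in normative table for a pediatric age (0-14 years).

    The printed literature block covers children up to ~4 years (2 years
    for tube sizes and tracheal ultrasonography); other pediatric ages
    return the same constants flagged as an approximate reference. The
    proximal-trachea diameter is sex-specific (7.3 mm boys, 6.5 mm girls);
    unspecified sex takes the smaller value.
    """
    if not (0 <= age_years <= 14):
        raise ValueError(
            f"age {age_years} outside the pediatric range [0, 14] years"
        )
    if sex not in _SEXES:
        raise ValueError(f"sex must be one of {_SEXES}, got {sex!r}")
    return _build(_load_builtin(), float(age_years), sex)


def load_reference(path, age_years: float, sex: str = "unspecified") -> AirwayReferenceSet:
    """User-supplied override table in the built-in JSON schema."""
    with open(path) as fh:
        return _build(json.load(fh), float(age_years), sex)


def _fmt(v: float | None, unit: str = "") -> str:
    return "n/a" if v is None else f"{v:g}{unit}"


def to_prompt_block(ref: AirwayReferenceSet) -> str:
    """Deterministic plain-text rendering for prompts and reports."""
    lines = [
        f"Normative pediatric airway dimensions "
        f"(age {ref.age_years:g} y, sex {ref.sex}; approximate anatomical "
        f"reference, table v{ref.version}):",
    ]
    for s in ref.sites:
        lines.append(
            f"- {s.site}: AP diameter {_fmt(s.ap_diameter_mm, ' mm')}"
            + (f" (SD {s.ap_sd_mm:g})" if s.ap_sd_mm is not None else "")
            + f", transverse {_fmt(s.transverse_diameter_mm, ' mm')}"
            + (f" (SD {s.transverse_sd_mm:g})" if s.transverse_sd_mm is not None else "")
            + f", cross-section {_fmt(s.cross_section_mm2, ' mm^2')}"
            + (f" [{s.source}]" if s.source else "")
        )
    lines.append(
        f"- endotracheal tube: internal {ref.ett_internal_mm[0]:g}-"
        f"{ref.ett_internal_mm[1]:g} mm, outer {ref.ett_outer_mm[0]:g}-"
        f"{ref.ett_outer_mm[1]:g} mm"
    )
    for note in ref.context_notes:
        lines.append(f"- note: {note}")
    return "\n".join(lines) + "\n"
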