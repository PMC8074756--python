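"""Cross-condition overlap arithmetic and the consolidated report.

The headline comparisons of an out-of-field (abscopal) radiation study are
set arithmetic on deregulation sets: Venn overlaps between exposure
modalities (partial-body PBI vs whole-body WBI), shared fractions of each
condition's set, signed percent changes of set sizes between time points,
and the physical dose reaching the shielded tissue. Feature identity is by
id string, case-insensitive by default (gene symbols are written in mixed
styles across figures); accession-keyed sets can opt out.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

__all__ = [
    "DeregulationSet",
    "VennSummary",
    "venn",
    "shared_fraction",
    "count_change",
    "shielded_dose",
    "build_report",
]


def _norm_id(feature: str, case_insensitive: bool) -> str:
    f = str(feature).strip()
    return f.casefold() if case_insensitive else f


@dataclass
class DeregulationSet:
    """A named set of deregulated features for one experimental condition
    (modality, dose, time point, omics layer), with per-member direction."""

    name: str
    members: set = field(default_factory=set)
    directions: dict = field(default_factory=dict)
    condition: dict = field(default_factory=dict)
    case_insensitive: bool = True

    def __post_init__(self) -> None:
        canon: dict[str, str] = {}
        for m in self.members:
            key = _norm_id(m, self.case_insensitive)
            if key in canon:
                raise ValueError(f"duplicate member {m!r} in set {self.name!r}")
            canon[key] = m
        self._canon = canon
        self.directions = {
            _norm_id(k, self.case_insensitive): v for k, v in self.directions.items()
        }

    @property
    def ids(self) -> frozenset:
        return frozenset(self._canon)

    def __len__(self) -> int:
        return len(self._canon)

    def __contains__(self, feature: str) -> bool:
        return _norm_id(feature, self.case_insensitive) in self._canon

    def direction(self, feature: str) -> str | None:
        return self.directions.get(_norm_id(feature, self.case_insensitive))


@dataclass
class VennSummary:
    """Exact region cardinalities for 2-4 sets.

    ``regions`` maps a membership pattern (tuple of booleans, one per set in
    input order, at least one True) to the features exclusive to exactly that
    combination; region counts therefore sum to the union size
    (inclusion-exclusion consistency by construction).
    """

    set_names: list
    set_sizes: dict
    regions: dict  # pattern tuple -> sorted member list
    intersections: dict  # subset name tuple -> size of their full intersection
    shared_percent: dict  # (subset tuple, set name) -> % of that set shared

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def region_count(self, pattern: tuple) -> int:
        return len(self.regions.get(tuple(pattern), ()))


def venn(sets: Sequence[DeregulationSet], ndigits: int = 0) -> VennSummary:
    """Exact Venn decomposition of 2-4 deregulation sets.

    Returns per-set sizes, exclusive-region member lists for every membership
    pattern, full-intersection sizes for every subset of >= 2 sets, and the
    shared fraction of each set relative to every intersection it enters.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn supports 2 to 4 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("deregulation sets must have distinct names")
    ids = [s.ids for s in sets]
    universe = frozenset().union(*ids)
    regions: dict[tuple, list] = {}
    for feature in universe:
        pattern = tuple(feature in s for s in ids)
        regions.setdefault(pattern, []).append(feature)
    regions = {k: sorted(v) for k, v in regions.items()}
    intersections: dict[tuple, int] = {}
    shared: dict[tuple, float] = {}
    for k in range(2, len(sets) + 1):
        for combo in combinations(range(len(sets)), k):
            inter = frozenset.intersection(*[ids[i] for i in combo])
            key = tuple(names[i] for i in combo)
            intersections[key] = len(inter)
            for i in combo:
                if len(ids[i]) > 0:
                    shared[(key, names[i])] = shared_fraction(
                        len(inter), len(ids[i]), ndigits=ndigits
                    )
    return VennSummary(
        set_names=names,
        set_sizes={n: len(s) for n, s in zip(names, sets)},
        regions=regions,
        intersections=intersections,
        shared_percent=shared,
    )


def shared_fraction(intersection_size: int, set_size: int,
                    ndigits: int = 0) -> float:
    """Percentage of a set contained in an intersection:
    100 * intersection / size, rounded to ``ndigits`` decimals (0 gives the
    integer-percent convention)."""
    if set_size <= 0:
        raise ValueError("set size must be > 0")
    if not 0 <= intersection_size <= set_size:
        raise ValueError("intersection size must be in [0, set size]")
    return round(100.0 * intersection_size / set_size, ndigits)


def count_change(count_later: float, count_earlier: float,
                 ndigits: int = 0) -> float:
    """Signed percent change of a set size between two time points:
    100 * (later - earlier)/earlier; negative values are decreases."""
    if count_earlier <= 0:
        raise ValueError("earlier count must be > 0")
    return round(100.0 * (count_later - count_earlier) / count_earlier, ndigits)


def shielded_dose(total_dose_gy: float, transmission_fraction: float) -> float:
    """Dose to shielded tissue in mGy: total dose (Gy) x transmission
    fraction x 1000."""
    if total_dose_gy < 0:
        raise ValueError("dose must be >= 0")
    if not 0 <= transmission_fraction <= 1:
        raise ValueError("transmission fraction must be in [0, 1]")
    return total_dose_gy * transmission_fraction * 1000.0


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 10):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_round_floats(v, sig) for v in sorted(obj, key=str)] \
            if isinstance(obj, (set, frozenset)) else [_round_floats(v, sig) for v in obj]
    return obj


def _venn_to_dict(v: VennSummary) -> dict:
    return {
        "set_names": v.set_names,
        "set_sizes": v.set_sizes,
        "union_size": v.union_size,
        "regions": {
            "+".join(n for n, m in zip(v.set_names, patt) if m): members
            for patt, members in sorted(v.regions.items())
        },
        "intersections": {" & ".join(k): n for k, n in v.intersections.items()},
        "shared_percent": {
            f"{' & '.join(key)} / {of}": pct
            for (key, of), pct in v.shared_percent.items()
        },
    }


_SECTIONS = ("deregulation", "venn", "shared_fractions", "time_course",
             "cls_weights", "neurogenesis", "dosimetry")


def build_report(stages: Mapping[str, object],
                 config: Mapping | None = None) -> dict:
    """Assemble the consolidated machine-readable report.

    ``stages`` maps section names (any of: deregulation, venn,
    shared_fractions, time_course, cls_weights, neurogenesis, dosimetry) to
    JSON-serializable content; ``VennSummary`` values are expanded. Missing
    sections are reported explicitly as absent. Floats are serialized at 10
    significant digits so reruns are byte-identical; the config hash makes
    every number traceable to its configuration.
    """
    if not any(k in stages for k in _SECTIONS):
        raise ValueError(f"no known stage output present; expected any of {_SECTIONS}")
    unknown = [k for k in stages if k not in _SECTIONS]
    if unknown:
        raise ValueError(f"unknown report sections: {unknown}")

    dereg = stages.get("deregulation")
    if dereg is not None:
        keys = {tuple(sorted(d.condition)) for d in dereg
                if isinstance(d, DeregulationSet)}
        if len(keys) > 1:
            raise ValueError(
                f"inconsistent condition keys across deregulation sets: {sorted(keys)}"
            )

    body: dict = {}
    for section in _SECTIONS:
        if section not in stages:
            body[section] = {"status": "absent"}
            continue
        value = stages[section]
        if section == "venn":
            value = {
                name: _venn_to_dict(v) if isinstance(v, VennSummary) else v
                for name, v in dict(value).items()
            }
        elif section == "deregulation":
            value = {
                d.name: {"condition": d.condition, "n": len(d),
                         "members": sorted(d.ids)}
                for d in value
            }
        body[section] = {"status": "present", "content": _round_floats(value)}

    config = dict(config or {})
    config_json = json.dumps(_round_floats(config), sort_keys=True)
    report = {
        "schema_version": "1.0",
        "config": config,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest()[:16],
        "sections": body,
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of a report built by :func:`build_report`."""
    lines = [f"# Analysis report (config {report['config_hash']})", ""]
    for section, payload in report["sections"].items():
        lines.append(f"## {section}")
        if payload["status"] == "absent":
            lines.append("_absent_")
        else:
            lines.append("```json")
            lines.append(json.dumps(payload["content"], indent=2, sort_keys=True))
            lines.append("```")
        lines.append("")
    return "\n".join(lines)
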