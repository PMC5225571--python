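"""ICD-9-CM code-to-category mapping.

Physical comorbidity categories are defined by inclusive ranges over the
3-digit code root (the ICD-9-CM chapter convention); psychiatric categories
by explicit dotted-code prefix sets.  A single code may carry one physical
and one or more psychiatric labels at once (e.g. organic sleep codes in the
327 block sit inside the nervous-system chapter), and substance use disorder
is the union of its subtype code sets.

The default map ships with the package as a YAML data file and can be
replaced wholesale with :func:`load_category_map`.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from dateutil.relativedelta import relativedelta

__all__ = [
    "CategoryMap",
    "load_category_map",
    "default_category_map",
    "categorize",
    "person_category_set",
    "in_window",
    "ICD9_CODE_RE",
]

#: Numeric ICD-9-CM grammar: 3-digit root, optional 1-2 decimal digits.
ICD9_CODE_RE = re.compile(r"^\d{3}(\.\d{1,2})?$")


def _norm(code: str) -> str:
    return code.replace(".", "")


@dataclass(frozen=True)
class CategoryMap:
    """Mapping of ICD-9-CM codes to analysis categories.

    Parameters
    ----------
    physical
        Sequence of ``(category_name, ranges)`` with inclusive 3-digit root
        ranges, e.g. ``("Respiratory system", ((460, 519),))``.
    psychiatric
        ``category_name -> dotted code prefixes``; a code matches when it
        equals a prefix or extends it with further digits.
    representative_codes
        ``category_name -> concrete codes``, used by the synthetic claims
        generator when emitting a diagnosis for a category.
    arm_items
        Category names forming the item universe for rule mining.
    index_code, index_label
        The index-disorder code and its transaction item label.
    """

    physical: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    psychiatric: Mapping[str, tuple[str, ...]]
    representative_codes: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    arm_items: tuple[str, ...] = ()
    index_code: str = "301.83"
    index_label: str = "BPD"

    def __post_init__(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, ranges in self.physical:
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"empty range {lo}-{hi} in category {name!r}")
                for plo, phi in seen:
                    if lo <= phi and plo <= hi:
                        raise ValueError(
                            f"overlapping physical ranges at category {name!r}"
                        )
                seen.append((lo, hi))
        for name, prefixes in self.psychiatric.items():
            if not prefixes:
                raise ValueError(f"psychiatric category {name!r} has no codes")

    @property
    def physical_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.physical)

    @property
    def psychiatric_names(self) -> tuple[str, ...]:
        return tuple(self.psychiatric)

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.physical_names + self.psychiatric_names


def _parse_map_dict(raw: Mapping) -> CategoryMap:
    physical = tuple(
        (entry["name"], tuple((int(lo), int(hi)) for lo, hi in entry["ranges"]))
        for entry in raw["physical"]
    )
    psychiatric = {}
    reps: dict[str, tuple[str, ...]] = {}
    for name, entry in raw["psychiatric"].items():
        if isinstance(entry, Mapping):
            psychiatric[name] = tuple(str(p) for p in entry["prefixes"])
            reps[name] = tuple(str(c) for c in entry.get("representative_codes", ()))
        else:  # plain list of codes
            psychiatric[name] = tuple(str(p) for p in entry)
            reps[name] = tuple(str(p) for p in entry)
    for entry in raw["physical"]:
        reps[entry["name"]] = tuple(
            str(c) for c in entry.get("representative_codes", ())
        )
    return CategoryMap(
        physical=physical,
        psychiatric=psychiatric,
        representative_codes=reps,
        arm_items=tuple(raw.get("arm_items", ())),
        index_code=str(raw.get("index_code", "301.83")),
        index_label=str(raw.get("index_label", "BPD")),
    )


def load_category_map(path) -> CategoryMap:
    """Load a category map from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _parse_map_dict(raw)


def default_category_map() -> CategoryMap:
    """The packaged default map (13 physical chapter ranges, conventional
    psychiatric groupings)."""
    ref = resources.files("comorbidarm.data").joinpath("default_categories.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _parse_map_dict(raw)


def categorize(icd9_code: str, cmap: CategoryMap) -> set[str]:
    """Return every category label carried by ``icd9_code``.

    V- and E-prefixed or otherwise malformed codes fall outside the numeric
    grammar and return the empty set with a warning.
    """
    code = str(icd9_code).strip()
    if not ICD9_CODE_RE.match(code):
        warnings.warn(
            f"code {code!r} does not match the numeric ICD-9-CM grammar; "
            "not assigned to any category",
            stacklevel=2,
        )
        return set()
    labels: set[str] = set()
    if code == cmap.index_code:
        labels.add(cmap.index_label)
    root = int(code[:3])
    for name, ranges in cmap.physical:
        if any(lo <= root <= hi for lo, hi in ranges):
            labels.add(name)
    ncode = _norm(code)
    for name, prefixes in cmap.psychiatric.items():
        if any(ncode.startswith(_norm(p)) for p in prefixes):
            labels.add(name)
    return labels


def in_window(diagnosis_date, index_date, window_years: float) -> bool:
    """Closed-boundary test: is the diagnosis within ``window_years`` of the
    index date?

    Integer windows use calendar-year arithmetic (3 years means the same
    month and day three years away, inclusive); fractional windows fall back
    to ``365.25 * window_years`` days.
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    d = pd.Timestamp(diagnosis_date)
    t = pd.Timestamp(index_date)
    if float(window_years).is_integer():
        off = relativedelta(years=int(window_years))
        return t - off <= d <= t + off
    delta = pd.Timedelta(days=365.25 * window_years)
    return abs(d - t) <= delta


def person_category_set(
    diagnoses,
    index_date,
    window_years: float,
    cmap: CategoryMap,
    items: Iterable[str] | None = None,
) -> set[str]:
    """Union of categories over a person's diagnoses within the comorbidity
    window around ``index_date``.

    ``diagnoses`` is a DataFrame with ``icd9_code`` and ``diagnosis_date``
    columns, or an iterable of ``(icd9_code, diagnosis_date)`` pairs.
    ``items``, when given, restricts the result to that label set.
    """
    if isinstance(diagnoses, pd.DataFrame):
        pairs: Sequence = list(
            zip(diagnoses["icd9_code"], diagnoses["diagnosis_date"])
        )
    else:
        pairs = list(diagnoses)
    out: set[str] = set()
    for code, date in pairs:
        if in_window(date, index_date, window_years):
            out |= categorize(code, cmap)
    if items is not None:
        out &= set(items)
    return out
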