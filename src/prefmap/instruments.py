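"""FACT-H&N scoring and the SF-6D health-state / tariff engine.

The FACT-H&N (Functional Assessment of Cancer Therapy -- Head & Neck)
is a disease-specific quality-of-life questionnaire with five domains
(PWB, SWB, EWB, FWB and the head-and-neck concerns subscale HNCS);
each item is answered on a 0-4 scale and domain scores are item sums
after reversal adjustment, with the total score the sum of the five
domains (higher = better quality of life).

The SF-6D is a preference-based classification with six dimensions
(physical functioning, role limitations, social functioning, pain,
mental health, vitality) of 6/4/5/6/5/5 levels; a *tariff* (value set)
converts a health state into a utility anchored at 1 for full health.
The Hong Kong SF-6Dv1 value set spans 0.315-1; the tariff shipped with
this package is a synthetic stand-in with that same structure and range
(see ``data/sf6d_tariff_hk_synthetic.json``).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACT_DOMAINS",
    "SF6D_DIMENSIONS",
    "SF6D_LEVEL_COUNTS",
    "FactProfile",
    "Sf6dState",
    "Tariff",
    "score_fact",
    "apply_tariff",
    "enumerate_states",
    "load_tariff",
    "save_tariff",
    "default_tariff",
]

#: FACT-H&N domains in canonical order, with default score maxima
#: following the FACIT item counts (7, 7, 6, 7, 10+ items at 0-4 each).
FACT_DOMAINS: dict[str, int] = {
    "pwb": 28,
    "swb": 28,
    "ewb": 24,
    "fwb": 28,
    "hncs": 40,
}

#: Default item counts per domain (FACIT convention; configurable).
FACT_ITEM_COUNTS: dict[str, int] = {
    "pwb": 7,
    "swb": 7,
    "ewb": 6,
    "fwb": 7,
    "hncs": 10,
}

#: SF-6D dimensions in the tariff's canonical order.
SF6D_DIMENSIONS: tuple[str, ...] = (
    "pf",  # physical functioning
    "rl",  # role limitations
    "sf",  # social functioning
    "pain",
    "mh",  # mental health
    "vit",  # vitality
)

#: SF-6Dv1 level counts per dimension: 6*4*5*6*5*5 = 18,000 states.
SF6D_LEVEL_COUNTS: tuple[int, ...] = (6, 4, 5, 6, 5, 5)

#: Nominal upper bound of the FACT-H&N total score; observed totals may
#: exceed it by a point on some versions, so violations warn, not error.
FACT_TOTAL_NOMINAL_MAX = 144


class InstrumentError(ValueError):
    """Validation failure in instrument scoring or tariff handling."""


@dataclass(frozen=True)
class FactProfile:
    """Five FACT-H&N domain scores and their total."""

    pwb: float
    swb: float
    ewb: float
    fwb: float
    hncs: float

    def __post_init__(self) -> None:
        for name, bound in FACT_DOMAINS.items():
            value = getattr(self, name)
            if not 0 <= value <= bound:
                raise InstrumentError(
                    f"domain {name!r} score {value} outside [0, {bound}]"
                )
        if self.total > FACT_TOTAL_NOMINAL_MAX:
            warnings.warn(
                f"FACT-H&N total {self.total} exceeds the nominal maximum "
                f"{FACT_TOTAL_NOMINAL_MAX}",
                stacklevel=2,
            )

    @property
    def total(self) -> float:
        return self.pwb + self.swb + self.ewb + self.fwb + self.hncs

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FACT_DOMAINS} | {
            "total": self.total
        }


@dataclass(frozen=True)
class Sf6dState:
    """A multi-dimension health state, levels 1 = best.

    Defaults to the SF-6D structure; ``level_counts`` may describe a toy
    classification (e.g. all-binary dimensions) for testing tariffs.
    """

    levels: tuple[int, ...]
    level_counts: tuple[int, ...] = SF6D_LEVEL_COUNTS

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.level_counts):
            raise InstrumentError(
                f"state has {len(self.levels)} dimensions, expected "
                f"{len(self.level_counts)}"
            )
        names = (
            SF6D_DIMENSIONS
            if self.level_counts == SF6D_LEVEL_COUNTS
            else tuple(f"dim{i + 1}" for i in range(len(self.level_counts)))
        )
        for dim, (level, count) in zip(names, zip(self.levels, self.level_counts)):
            if not 1 <= level <= count:
                raise InstrumentError(
                    f"dimension {dim!r}: level {level} outside 1..{count}"
                )

    @classmethod
    def best(cls, level_counts: tuple[int, ...] = SF6D_LEVEL_COUNTS) -> "Sf6dState":
        return cls(tuple(1 for _ in level_counts), level_counts)

    @classmethod
    def worst(cls, level_counts: tuple[int, ...] = SF6D_LEVEL_COUNTS) -> "Sf6dState":
        return cls(tuple(level_counts), level_counts)


@dataclass(frozen=True)
class GlobalTerm:
    """An extra tariff decrement triggered by per-dimension level thresholds.

    ``min_levels`` maps dimension name -> minimum level; the term applies
    when every listed dimension is at or beyond its threshold (the SF-6D
    "MOST" term is of this form).
    """

    min_levels: Mapping[str, int]
    value: float

    def applies(self, state: Sf6dState) -> bool:
        idx = {d: i for i, d in enumerate(SF6D_DIMENSIONS)}
        return all(
            state.levels[idx[dim]] >= level
            for dim, level in self.min_levels.items()
        )


@dataclass(frozen=True)
class Tariff:
    """An SF-6D value set: constant plus per-dimension level decrements.

    utility(state) = constant + sum of decrements + applicable global terms.
    The all-best state must evaluate to 1 and ``floor`` must equal the
    minimum utility over all enumerable states.
    """

    name: str
    constant: float
    decrements: tuple[tuple[float, ...], ...]  # [dimension][level-1]
    floor: float
    global_terms: tuple[GlobalTerm, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.decrements:
            raise InstrumentError(f"tariff {self.name!r} has no dimensions")
        names = (
            SF6D_DIMENSIONS
            if self.level_counts == SF6D_LEVEL_COUNTS
            else tuple(f"dim{i + 1}" for i in range(len(self.decrements)))
        )
        for dim, decs in zip(names, self.decrements):
            if decs[0] != 0:
                raise InstrumentError(
                    f"dimension {dim!r}: level-1 decrement must be 0, got {decs[0]}"
                )
            if any(d > 0 for d in decs[1:]):
                raise InstrumentError(
                    f"dimension {dim!r}: decrements beyond level 1 must be <= 0"
                )
        best = self.constant  # no decrements, no global terms at all-best
        if abs(best - 1.0) > 1e-9:
            raise InstrumentError(
                f"tariff {self.name!r}: all-best utility {best} != 1"
            )

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.decrements)

    def validate_floor(self) -> None:
        """Check ``floor`` equals the minimum utility over all states."""
        utilities = [apply_tariff(s, self) for s in enumerate_states(self)]
        observed = min(utilities)
        if abs(observed - self.floor) > 1e-9:
            raise InstrumentError(
                f"tariff {self.name!r}: declared floor {self.floor} but "
                f"minimum enumerated utility is {observed}"
            )


def score_fact(
    items: Mapping[str, Sequence[int]] | None = None,
    domains: Mapping[str, float] | None = None,
    reversal_map: Iterable[tuple[str, int]] = (),
) -> FactProfile:
    """Score the FACT-H&N from item responses or ready domain scores.

    Parameters
    ----------
    items
        Mapping domain name -> ordinal item responses in {0,...,4}.
        Reverse-scored items (identified by ``(domain, index)`` pairs in
        ``reversal_map``) are mapped r -> 4 - r before summation.
    domains
        Mapping domain name -> pre-computed domain score; used when
        item-level data are unavailable. Exactly one of ``items`` /
        ``domains`` must be given.
    """
    if (items is None) == (domains is None):
        raise InstrumentError("supply exactly one of items= or domains=")
    if domains is not None:
        missing = set(FACT_DOMAINS) - set(domains)
        if missing:
            raise InstrumentError(f"missing domain scores: {sorted(missing)}")
        return FactProfile(**{d: float(domains[d]) for d in FACT_DOMAINS})

    assert items is not None
    reversed_items = set(reversal_map)
    scores: dict[str, float] = {}
    for domain in FACT_DOMAINS:
        if domain not in items:
            raise InstrumentError(f"missing item responses for domain {domain!r}")
        total = 0
        for i, response in enumerate(items[domain]):
            if response is None:
                raise InstrumentError(
                    f"domain {domain!r} item {i}: missing response (no imputation)"
                )
            if response not in (0, 1, 2, 3, 4):
                raise InstrumentError(
                    f"domain {domain!r} item {i}: response {response!r} "
                    "outside 0..4"
                )
            total += 4 - response if (domain, i) in reversed_items else response
        scores[domain] = float(total)
    return FactProfile(**scores)


def apply_tariff(state: Sf6dState, tariff: Tariff) -> float:
    """Utility of a health state under a tariff."""
    if state.level_counts != tariff.level_counts:
        raise InstrumentError(
            f"state structure {state.level_counts} does not match tariff "
            f"{tariff.name!r} structure {tariff.level_counts}"
        )
    u = tariff.constant
    for dim_index, level in enumerate(state.levels):
        u += tariff.decrements[dim_index][level - 1]
    for term in tariff.global_terms:
        if term.applies(state):
            u += term.value
    return u


def apply_tariff_frame(levels: pd.DataFrame, tariff: Tariff) -> np.ndarray:
    """Vectorised tariff application to columns sf6d_<dim> of a frame."""
    n = len(levels)
    u = np.full(n, tariff.constant)
    for dim_index, dim in enumerate(SF6D_DIMENSIONS):
        decs = np.asarray(tariff.decrements[dim_index])
        lev = levels[f"sf6d_{dim}"].to_numpy(dtype=int)
        if lev.min() < 1 or lev.max() > SF6D_LEVEL_COUNTS[dim_index]:
            raise InstrumentError(f"dimension {dim!r}: level out of range")
        u += decs[lev - 1]
    if tariff.global_terms:
        idx = {d: i for i, d in enumerate(SF6D_DIMENSIONS)}
        for term in tariff.global_terms:
            mask = np.ones(n, dtype=bool)
            for dim, min_level in term.min_levels.items():
                mask &= levels[f"sf6d_{dim}"].to_numpy(dtype=int) >= min_level
            u[mask] += term.value
    return u


def enumerate_states(tariff: Tariff | None = None) -> list[Sf6dState]:
    """All health states in lexicographic order (best state first)."""
    counts = SF6D_LEVEL_COUNTS if tariff is None else tariff.level_counts
    return [
        Sf6dState(levels, counts)
        for levels in itertools.product(*(range(1, c + 1) for c in counts))
    ]


def load_tariff(path: str | Path) -> Tariff:
    """Load and validate a tariff from its JSON schema.

    Schema: ``{name, constant, dimensions: [{name, levels, decrements}],
    global_terms: [{condition, value}], floor}``.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return _tariff_from_dict(raw, source=str(path))


def _tariff_from_dict(raw: Mapping, source: str = "<dict>") -> Tariff:
    for key in ("name", "constant", "dimensions", "floor"):
        if key not in raw:
            raise InstrumentError(f"{source}: tariff file missing key {key!r}")
    dims = raw["dimensions"]
    names = [d.get("name") for d in dims]
    missing = [d for d in SF6D_DIMENSIONS if d not in names]
    if missing:
        raise InstrumentError(f"{source}: missing dimension(s) {missing}")
    by_name = {d["name"]: d for d in dims}
    decrements = []
    for dim, count in zip(SF6D_DIMENSIONS, SF6D_LEVEL_COUNTS):
        entry = by_name[dim]
        if entry.get("levels") != count or len(entry["decrements"]) != count:
            raise InstrumentError(
                f"{source}: dimensions[{dim}]: expected {count} levels"
            )
        decrements.append(tuple(float(x) for x in entry["decrements"]))
    terms = tuple(
        GlobalTerm(min_levels=t["condition"], value=float(t["value"]))
        for t in raw.get("global_terms", [])
    )
    tariff = Tariff(
        name=raw["name"],
        constant=float(raw["constant"]),
        decrements=tuple(decrements),
        floor=float(raw["floor"]),
        global_terms=terms,
    )
    tariff.validate_floor()
    return tariff


def save_tariff(tariff: Tariff, path: str | Path) -> None:
    raw = {
        "name": tariff.name,
        "constant": tariff.constant,
        "dimensions": [
            {"name": dim, "levels": len(decs), "decrements": list(decs)}
            for dim, decs in zip(SF6D_DIMENSIONS, tariff.decrements)
        ],
        "global_terms": [
            {"condition": dict(t.min_levels), "value": t.value}
            for t in tariff.global_terms
        ],
        "floor": tariff.floor,
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2)


def default_tariff() -> Tariff:
    """The packaged synthetic HK-like SF-6D tariff (floor 0.315)."""
    raw = json.loads(
        resources.files("prefmap.data")
        .joinpath("sf6d_tariff_hk_synthetic.json")
        .read_text()
    )
    return _tariff_from_dict(raw, source="packaged tariff")
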