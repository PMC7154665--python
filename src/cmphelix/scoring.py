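"""Four-category triple-helix suitability rubric.

A diproline module is judged on four categories — main-chain preorganization,
Yyy ring-flip preference, adaptability to small torsion fluctuations, and
steric toleration inside the triple helix — each marked "+" (above average),
"o" (average) or "-" (below average).  The marks are combined into a summed
score S whose symbol (++/+/o/-/--) tracks the experimentally measured
transition temperatures of the corresponding collagen model peptides.

The shipped default weights are a minimal-complexity integer assignment that
reproduces the published S column for all thirteen modules: every mark
contributes +1/0/-1 except that a "-" in the main-chain or sterics category
counts -2, reflecting that a poorly preorganized main chain or a steric
clash is more damaging than, say, a suboptimal ring-flip preference.  The
plain +-1 sum remains selectable as ``NAIVE_WEIGHTS``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import reference
from .errors import ScoringError

CATEGORIES = ("main_chain", "ring_flip", "adaptability", "sterics")
MARKS = ("+", "o", "-")

# unicode variants seen in typeset tables
_MARK_ALIASES = {"−": "-", "–": "-", "—": "-", "−−": "--"}


def normalize_mark(mark: str) -> str:
    mark = _MARK_ALIASES.get(mark, mark).strip()
    mark = "".join(_MARK_ALIASES.get(ch, ch) for ch in mark)
    if mark not in MARKS:
        raise ScoringError(f"unknown mark {mark!r} (expected one of {MARKS})")
    return mark


@dataclass(frozen=True)
class CategoryMarks:
    main_chain: str
    ring_flip: str
    adaptability: str
    sterics: str

    def __post_init__(self):
        for cat in CATEGORIES:
            object.__setattr__(self, cat, normalize_mark(getattr(self, cat)))

    def as_dict(self) -> dict[str, str]:
        return {cat: getattr(self, cat) for cat in CATEGORIES}


@dataclass
class SuitabilityScore:
    marks: CategoryMarks
    s_numeric: int
    s_symbol: str
    tm: float | None = None
    name: str = ""


#: Default weights: +-1/0 with "-" in main_chain and sterics counting -2.
DEFAULT_WEIGHTS: dict[str, dict[str, int]] = {
    "main_chain": {"+": 1, "o": 0, "-": -2},
    "ring_flip": {"+": 1, "o": 0, "-": -1},
    "adaptability": {"+": 1, "o": 0, "-": -1},
    "sterics": {"+": 1, "o": 0, "-": -2},
}

#: Plain symmetric sum: every mark +1/0/-1 regardless of category.
NAIVE_WEIGHTS: dict[str, dict[str, int]] = {
    cat: {"+": 1, "o": 0, "-": -1} for cat in CATEGORIES
}

#: Score bands mapping the integer sum to the printed symbol.
DEFAULT_BANDS = ((2, "++"), (1, "+"), (0, "o"), (-3, "-"), (-1000, "--"))


def symbol_for(s_numeric: int, bands=DEFAULT_BANDS) -> str:
    for floor, symbol in bands:
        if s_numeric >= floor:
            return symbol
    return bands[-1][1]


# thresholds for the quantitative -> mark mapping (degrees / counts)
MAINCHAIN_PLUS_BELOW = 10.0
MAINCHAIN_O_BELOW = 15.0


def assign_marks(
    max_mainchain_deviation: float,
    flip_label: str,
    adaptability_class: str,
    clash_count: int,
) -> CategoryMarks:
    """Map quantitative module outputs to the four category marks.

    Main chain: "+" below 10 deg maximum deviation from the (PPG)10 means,
    "o" below 15 deg, "-" otherwise.  Ring flip: exo-preferring -> "+",
    balanced -> "o", endo-preferring -> "-".  Sterics: "-" for any
    inter-strand clash, "o" otherwise.  Adaptability has no quantitative
    definition and is passed through as a user-supplied mark.
    """
    if max_mainchain_deviation is None or flip_label is None or clash_count is None:
        raise ScoringError("all four metrics must be supplied")
    if max_mainchain_deviation < MAINCHAIN_PLUS_BELOW:
        main_chain = "+"
    elif max_mainchain_deviation < MAINCHAIN_O_BELOW:
        main_chain = "o"
    else:
        main_chain = "-"
    flip_map = {"exo-preferring": "+", "balanced": "o", "endo-preferring": "-"}
    if flip_label not in flip_map:
        raise ScoringError(f"unknown ring-flip label {flip_label!r}")
    sterics = "-" if clash_count > 0 else "o"
    return CategoryMarks(main_chain, flip_map[flip_label], normalize_mark(adaptability_class), sterics)


def sum_score(
    marks: CategoryMarks,
    weights: dict[str, dict[str, int]] | None = None,
    bands=DEFAULT_BANDS,
    tm: float | None = None,
    name: str = "",
) -> SuitabilityScore:
    """Combine category marks into the summed suitability score S."""
    weights = DEFAULT_WEIGHTS if weights is None else weights
    total = 0
    for cat in CATEGORIES:
        mark = getattr(marks, cat)
        try:
            total += weights[cat][mark]
        except KeyError as exc:
            raise ScoringError(f"no weight for ({cat}, {mark!r})") from exc
    return SuitabilityScore(marks, total, symbol_for(total, bands), tm=tm, name=name)


def correlate_with_tm(scores: list[SuitabilityScore]) -> float:
    """Spearman rank correlation of s_numeric vs Tm (ties mid-ranked)."""
    pairs = [(sc.s_numeric, sc.tm) for sc in scores if sc.tm is not None]
    if len(pairs) < 3:
        raise ScoringError("need at least 3 scores with Tm set")
    s, tm = zip(*pairs)
    if len(set(s)) == 1 or len(set(tm)) == 1:
        raise ScoringError("correlation undefined: all ranks tied")
    rho = stats.spearmanr(s, tm).statistic
    if np.isnan(rho):
        raise ScoringError("correlation undefined")
    return float(rho)


def score_reference_table(
    weights: dict[str, dict[str, int]] | None = None,
) -> list[SuitabilityScore]:
    """Score the published 13-module ranking table with the given weights."""
    out = []
    for name, mc, rf, ad, st, _sym, tm in reference.RANKING_TABLE:
        out.append(sum_score(CategoryMarks(mc, rf, ad, st), weights, tm=tm, name=name))
    return out


def reproduction_count(
    weights: dict[str, dict[str, int]] | None = None,
) -> tuple[int, list[str]]:
    """How many of the 13 published S symbols the weights reproduce."""
    mismatches = []
    for sc, row in zip(score_reference_table(weights), reference.RANKING_TABLE):
        printed = row[5]
        if sc.s_symbol != printed:
            mismatches.append(sc.name)
    return len(reference.RANKING_TABLE) - len(mismatches), mismatches
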