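"""Reading, cleaning, and structuring verbal fluency data.

Fluency data arrive as a CSV with one response per row, in chronological
order within each list.  Required columns are ``id`` (subject identifier),
``listnum`` (list identifier, unique within subject) and ``item`` (the
response).  Optional columns are ``category``, ``group`` and ``rt``
(inter-item response time); any further columns are ignored.

Cleaning happens in a fixed order: lowercasing/trimming (and optional
removal of non-alphabetic characters), then spell/canonicalization
corrections, then verbatim perseveration removal, then intrusion removal.
Applying corrections before deduplication matters: a spell file that maps
synonyms onto one canonical token turns near-repeats into verbatim repeats,
which is the behaviour experimenters rely on.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FluencyList",
    "FluencyDataset",
    "SpellMap",
    "Scheme",
    "FluencyFormatError",
    "load_fluency_data",
    "save_fluency_data",
    "set_hierarchy",
    "remove_intrusions_from_list",
]

REQUIRED_COLUMNS = ("id", "listnum", "item")
OPTIONAL_COLUMNS = ("category", "group", "rt")


class FluencyFormatError(ValueError):
    """Raised when an input file violates the documented format."""


@dataclass(frozen=True)
class FluencyList:
    """One subject's ordered responses for a single fluency probe."""

    subject_id: str
    list_number: int
    tokens: tuple[str, ...]
    category: str = ""
    rts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.rts is not None and len(self.rts) != len(self.tokens):
            raise ValueError(
                f"rts length {len(self.rts)} != tokens length {len(self.tokens)} "
                f"for subject {self.subject_id} list {self.list_number}"
            )


@dataclass(frozen=True)
class SpellMap:
    """Canonicalization dictionary: variant spelling -> canonical token.

    The file format is two columns, ``correct-spelling,incorrect-spelling``,
    no header.  Chains (a->b where b is itself corrected to c) are rejected
    at load time rather than resolved: silent transitive rewriting hides
    coding errors in the dictionary.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for bad, good in self.mapping.items():
            if bad == good:
                raise FluencyFormatError(f"spell entry maps {bad!r} to itself")
            if good in self.mapping:
                raise FluencyFormatError(
                    f"spell map chain: {bad!r} -> {good!r} -> {self.mapping[good]!r}; "
                    "targets may not themselves be corrected"
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpellMap":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 2:
                    raise FluencyFormatError(
                        f"{path}:{lineno}: expected correct-spelling,incorrect-spelling"
                    )
                good, bad = row[0].strip().lower(), row[1].strip().lower()
                mapping[bad] = good
        return cls(mapping)

    def correct(self, token: str) -> str:
        return self.mapping.get(token, token)


@dataclass(frozen=True)
class Scheme:
    """Category scheme assigning one or more labels to each allowable word.

    Two kinds exist.  A *semantic* scheme is loaded from a two-column CSV of
    ``category-label,member`` rows; a word may carry several labels.  A
    *letter-prefix* scheme labels each word by its first ``prefix_length``
    characters and accepts every word, mirroring how letter fluency data
    are clustered.
    """

    kind: str  # "semantic" | "letter-prefix"
    categories: Mapping[str, frozenset[str]] = field(default_factory=dict)
    prefix_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("semantic", "letter-prefix"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if self.kind == "letter-prefix" and (
            self.prefix_length is None or self.prefix_length < 1
        ):
            raise ValueError("letter-prefix scheme requires prefix_length >= 1")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Scheme":
        cats: dict[str, set[str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 2:
                    raise FluencyFormatError(
                        f"{path}:{lineno}: expected category-label,member"
                    )
                label, member = row[0].strip(), row[1].strip().lower()
                cats.setdefault(label, set()).add(member)
        return cls("semantic", {k: frozenset(v) for k, v in cats.items()})

    @classmethod
    def letter(cls, prefix_length: int) -> "Scheme":
        return cls("letter-prefix", {}, prefix_length)

    @property
    def inverted(self) -> Mapping[str, frozenset[str]]:
        """Word -> set of category labels (semantic schemes only)."""
        if self.kind != "semantic":
            raise ValueError("inverted index only defined for semantic schemes")
        inv: dict[str, set[str]] = {}
        for label, members in self.categories.items():
            for m in members:
                inv.setdefault(m, set()).add(label)
        return {w: frozenset(ls) for w, ls in inv.items()}

    def labels(self, word: str) -> frozenset[str]:
        """Label set for a word; empty if the word is unknown to the scheme."""
        if self.kind == "letter-prefix":
            return frozenset({word[: self.prefix_length]}) if word else frozenset()
        out: set[str] = set()
        for label, members in self.categories.items():
            if word in members:
                out.add(label)
        return frozenset(out)

    def is_member(self, word: str) -> bool:
        if self.kind == "letter-prefix":
            return True
        return any(word in members for members in self.categories.values())


def remove_intrusions_from_list(
    tokens: Sequence[str], scheme_or_letter: "Scheme | str"
) -> tuple[list[str], list[str]]:
    """Split tokens into (kept, removed) by category membership.

    With a semantic scheme, a token is kept iff it belongs to at least one
    category.  With a single target letter (letter fluency), a token is
    kept iff it begins with that letter.  Order is preserved.
    """
    if isinstance(scheme_or_letter, str):
        if len(scheme_or_letter) != 1:
            raise ValueError("target letter must be a single character")
        letter = scheme_or_letter.lower()
        ok = lambda t: t.startswith(letter)  # noqa: E731
    else:
        ok = scheme_or_letter.is_member
    kept, removed = [], []
    for t in tokens:
        (kept if ok(t) else removed).append(t)
    return kept, removed


@dataclass(frozen=True)
class FluencyDataset:
    """A collection of fluency lists with subject/group metadata.

    When ``hierarchical`` is True, measures aggregate to one value per
    subject (the unweighted mean across that subject's lists); when False
    each list is treated independently.  Lists are ordered first by subject
    (lexicographically) and then by list number (numerically).
    """

    lists: tuple[FluencyList, ...]
    hierarchical: bool = False
    group_assignments: Mapping[str, str] = field(default_factory=dict)
    # provenance of the cleaning pipeline, for summary reporting
    corrections_applied: tuple[dict, ...] = ()
    removed_perseverations: tuple[dict, ...] = ()
    removed_intrusions: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        keys = [(fl.subject_id, fl.list_number) for fl in self.lists]
        if keys != sorted(keys):
            raise ValueError("lists must be sorted by subject then list number")
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, listnum) pair")

    @property
    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for fl in self.lists:
            seen.setdefault(fl.subject_id)
        return tuple(seen)

    @property
    def listnums(self) -> tuple[tuple[str, int], ...]:
        return tuple((fl.subject_id, fl.list_number) for fl in self.lists)

    @property
    def item_index(self) -> dict[str, int]:
        """Bijection token -> integer, in order of first appearance."""
        idx: dict[str, int] = {}
        for fl in self.lists:
            for t in fl.tokens:
                if t not in idx:
                    idx[t] = len(idx)
        return idx

    @property
    def group_numnodes(self) -> int:
        """Number of distinct tokens across the whole dataset."""
        return len(self.item_index)

    @property
    def numnodes(self) -> dict[str, int]:
        """Distinct-token count per subject."""
        out: dict[str, set[str]] = {}
        for fl in self.lists:
            out.setdefault(fl.subject_id, set()).update(fl.tokens)
        return {s: len(v) for s, v in out.items()}

    def labeled_lists(self) -> list[list[str]]:
        return [list(fl.tokens) for fl in self.lists]

    def aggregate(self, per_list: Sequence[float]) -> pd.Series:
        """Per-list values -> the dataset's reporting granularity.

        Flat: a Series indexed by (subject, listnum).  Hierarchical: the
        unweighted mean of each subject's per-list values.
        """
        if len(per_list) != len(self.lists):
            raise ValueError("one value per list required")
        idx = pd.MultiIndex.from_tuples(self.listnums, names=["id", "listnum"])
        s = pd.Series(list(per_list), index=idx, dtype=float)
        if not self.hierarchical:
            return s
        return s.groupby(level="id", sort=False).mean()


def set_hierarchy(dataset: FluencyDataset, hierarchical: bool) -> FluencyDataset:
    """Return the same data under a different aggregation mode."""
    return replace(dataset, hierarchical=bool(hierarchical))


def _clean_token(raw: str, remove_nonalpha: bool) -> str:
    t = raw.strip().lower()
    if remove_nonalpha:
        t = "".join(ch for ch in t if ch.isalpha())
    return t


def load_fluency_data(
    path: str | Path,
    *,
    subjects: Iterable[str] | None = None,
    groups: Iterable[str] | None = None,
    categories: Iterable[str] | None = None,
    spell: "SpellMap | str | Path | None" = None,
    remove_perseverations: bool = False,
    remove_intrusions: bool = False,
    scheme: "Scheme | str | Path | None" = None,
    target_letter: str | None = None,
    remove_nonalpha: bool = False,
    hierarchical: bool = False,
) -> FluencyDataset:
    """Load a fluency CSV into a :class:`FluencyDataset`.

    Filters (``subjects``, ``groups``, ``categories``) select rows before
    any cleaning.  Cleaning order is fixed: lowercase/trim (and optional
    non-alpha stripping), spell corrections, verbatim perseveration
    removal, intrusion removal.  ``remove_intrusions`` requires a scheme or
    a target letter, since a list of allowable responses is needed.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FluencyFormatError(f"missing required column {col!r} in {path}")

    if isinstance(spell, (str, Path)):
        spell = SpellMap.from_csv(spell)
    if isinstance(scheme, (str, Path)):
        scheme = Scheme.from_csv(scheme)
    if remove_intrusions and scheme is None and target_letter is None:
        raise ValueError(
            "remove_intrusions requires a scheme file or a target letter: "
            "a list of allowable responses must be provided"
        )

    def _filter(col: str, allowed: Iterable[str] | None, label: str) -> None:
        nonlocal df
        if allowed is None:
            return
        allowed = set(allowed)
        if col not in df.columns:
            raise FluencyFormatError(
                f"cannot filter by {label}: column {col!r} absent from {path}"
            )
        df = df[df[col].isin(allowed)]
        if df.empty:
            warnings.warn(f"{label} filter {sorted(allowed)} selected no rows")

    _filter("id", subjects, "subject")
    _filter("group", groups, "group")
    _filter("category", categories, "category")

    group_assignments: dict[str, str] = {}
    if "group" in df.columns:
        for sid, g in zip(df["id"], df["group"]):
            if g:
                group_assignments[sid] = g

    corrections: list[dict] = []
    persev_removed: list[dict] = []
    intr_removed: list[dict] = []
    built: list[FluencyList] = []

    has_rt = "rt" in df.columns
    has_cat = "category" in df.columns
    keys = sorted(
        {(sid, int(ln)) for sid, ln in zip(df["id"], df["listnum"])},
        key=lambda k: (k[0], k[1]),
    )
    by_key = {k: [] for k in keys}
    for _, row in df.iterrows():
        by_key[(row["id"], int(row["listnum"]))].append(row)

    for (sid, ln) in keys:
        rows = by_key[(sid, ln)]
        toks = [_clean_token(r["item"], remove_nonalpha) for r in rows]
        rts = [float(r["rt"]) if r["rt"] != "" else float("nan") for r in rows] if has_rt else None
        cat = next((r["category"] for r in rows if has_cat and r["category"]), "")

        if spell is not None:
            fixed = []
            for pos, t in enumerate(toks):
                c = spell.correct(t)
                if c != t:
                    corrections.append(
                        {"id": sid, "listnum": ln, "position": pos, "from": t, "to": c}
                    )
                fixed.append(c)
            toks = fixed

        if remove_perseverations:
            seen: set[str] = set()
            kept_idx = []
            for pos, t in enumerate(toks):
                if t in seen:
                    persev_removed.append(
                        {"id": sid, "listnum": ln, "position": pos, "token": t}
                    )
                else:
                    seen.add(t)
                    kept_idx.append(pos)
            toks = [toks[i] for i in kept_idx]
            if rts is not None:
                rts = [rts[i] for i in kept_idx]

        if remove_intrusions:
            checker: Scheme | str = scheme if scheme is not None else target_letter  # type: ignore[assignment]
            kept_idx = []
            for pos, t in enumerate(toks):
                kept, _ = remove_intrusions_from_list([t], checker)
                if kept:
                    kept_idx.append(pos)
                else:
                    intr_removed.append(
                        {"id": sid, "listnum": ln, "position": pos, "token": t}
                    )
            toks = [toks[i] for i in kept_idx]
            if rts is not None:
                rts = [rts[i] for i in kept_idx]

        built.append(
            FluencyList(
                subject_id=sid,
                list_number=ln,
                tokens=tuple(toks),
                category=cat,
                rts=tuple(rts) if rts is not None else None,
            )
        )

    return FluencyDataset(
        lists=tuple(built),
        hierarchical=hierarchical,
        group_assignments=group_assignments,
        corrections_applied=tuple(corrections),
        removed_perseverations=tuple(persev_removed),
        removed_intrusions=tuple(intr_removed),
    )


def save_fluency_data(dataset: FluencyDataset, path: str | Path) -> None:
    """Write a dataset back to the standard fluency CSV."""
    rows = []
    for fl in dataset.lists:
        for pos, t in enumerate(fl.tokens):
            row = {"id": fl.subject_id, "listnum": fl.list_number, "item": t}
            if fl.category:
                row["category"] = fl.category
            g = dataset.group_assignments.get(fl.subject_id)
            if g:
                row["group"] = g
            if fl.rts is not None:
                row["rt"] = fl.rts[pos]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
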