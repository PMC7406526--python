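"""Traditional fluency statistics.

Covers the measures clinicians and memory researchers report from a
fluency list: cluster segmentation (fluid and static), cluster switches
and switch rate, average cluster size, perseveration and intrusion counts,
and word-level statistics (frequency, age of acquisition, or any
word -> value norm table).

Two clustering criteria are supported.  Under the *fluid* criterion a new
cluster begins whenever a response shares no category label with the
immediately preceding response.  Under the *static* criterion a new
cluster begins whenever a response shares no label common to every
response since the start of the current cluster (a running intersection of
label sets).  Static segmentation is at least as strict, so it never
yields fewer switches than fluid segmentation on the same list.

Responses absent from the scheme carry a unique singleton label: they
break clusters on both sides and form their own cluster, making unknown
words visible in the scores rather than silently fused into neighbours.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fluency_io import FluencyDataset, Scheme, remove_intrusions_from_list

__all__ = [
    "ClusterSegmentation",
    "NormTable",
    "segment_clusters",
    "cluster_switches",
    "cluster_sizes",
    "perseverations",
    "intrusions",
    "word_stat",
]


@dataclass(frozen=True)
class ClusterSegmentation:
    """Partition of a fluency list into contiguous clusters."""

    clusters: tuple[tuple[str, ...], ...]
    mode: str  # "fluid" | "static"

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Positions where a new cluster begins (position 0 implicit)."""
        out, pos = [], 0
        for c in self.clusters[:-1]:
            pos += len(c)
            out.append(pos)
        return tuple(out)

    @property
    def n_switches(self) -> int:
        return max(len(self.clusters) - 1, 0)

    @property
    def mean_cluster_size(self) -> float:
        if not self.clusters:
            return float("nan")
        return sum(len(c) for c in self.clusters) / len(self.clusters)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(t for c in self.clusters for t in c)


def _labelsets(tokens: Sequence[str], scheme: Scheme) -> list[frozenset]:
    """Label set per token; unknown tokens get a unique per-position label."""
    out: list[frozenset] = []
    unknown: list[str] = []
    for pos, t in enumerate(tokens):
        ls = scheme.labels(t)
        if not ls:
            unknown.append(t)
            ls = frozenset({("__unknown__", pos)})
        out.append(ls)
    if unknown:
        warnings.warn(
            "tokens not in scheme treated as singleton clusters: "
            + ", ".join(sorted(set(unknown)))
        )
    return out


def segment_clusters(
    tokens: Sequence[str], scheme: Scheme, mode: str = "fluid"
) -> ClusterSegmentation:
    """Segment a list into clusters under the fluid or static criterion.

    Fluid: a boundary precedes token *t* iff its label set shares nothing
    with the previous token's.  Static: a running intersection of label
    sets is kept over the current cluster; a boundary precedes *t* iff its
    labels miss that intersection entirely, and *t* then starts the next
    cluster.
    """
    if mode not in ("fluid", "static"):
        raise ValueError(f"mode must be 'fluid' or 'static', got {mode!r}")
    if not tokens:
        return ClusterSegmentation(clusters=(), mode=mode)
    labels = _labelsets(tokens, scheme)
    clusters: list[list[str]] = [[tokens[0]]]
    running = labels[0]  # static: common labels of the current cluster
    prev_ls = labels[0]  # fluid: previous token's labels
    for t, ls in zip(tokens[1:], labels[1:]):
        shared = ls & (prev_ls if mode == "fluid" else running)
        if shared:
            clusters[-1].append(t)
            if mode == "static":
                running = shared
        else:
            clusters.append([t])
            running = ls
        prev_ls = ls
    return ClusterSegmentation(
        clusters=tuple(tuple(c) for c in clusters), mode=mode
    )


def _resolve_scheme(scheme_or_prefixlen: "Scheme | int") -> Scheme:
    if isinstance(scheme_or_prefixlen, Scheme):
        return scheme_or_prefixlen
    n = int(scheme_or_prefixlen)
    if n < 1:
        raise ValueError("letter-prefix length must be >= 1")
    return Scheme.letter(n)


def cluster_switches(
    dataset: FluencyDataset,
    scheme_or_prefixlen: "Scheme | int",
    mode: str = "fluid",
    switch_rate: bool = False,
) -> pd.Series:
    """Cluster switches per list, or switches per item if ``switch_rate``.

    An integer argument synthesizes a letter-prefix scheme of that length.
    Hierarchical datasets return the per-subject mean.
    """
    scheme = _resolve_scheme(scheme_or_prefixlen)
    vals = []
    for fl in dataset.lists:
        seg = segment_clusters(fl.tokens, scheme, mode)
        v = float(seg.n_switches)
        if switch_rate:
            v = v / len(fl.tokens) if fl.tokens else 0.0
        vals.append(v)
    return dataset.aggregate(vals)


def cluster_sizes(
    dataset: FluencyDataset,
    scheme_or_prefixlen: "Scheme | int",
    mode: str = "fluid",
) -> pd.Series:
    """Mean cluster size (responses per cluster) per list or per subject."""
    scheme = _resolve_scheme(scheme_or_prefixlen)
    vals = [
        segment_clusters(fl.tokens, scheme, mode).mean_cluster_size
        for fl in dataset.lists
    ]
    return dataset.aggregate(vals)


def _perseverations_in(tokens: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for t in tokens:
        if t in seen:
            out.append(t)
        else:
            seen.add(t)
    return out


def perseverations(dataset: FluencyDataset, as_list: bool = False):
    """Verbatim within-list repetitions.

    Every occurrence beyond a token's first counts, so ``[dog, cat, dog,
    dog]`` has two perseverations.  Spell corrections were applied at load
    time, so canonicalized variants (e.g. two elephant subspecies mapped
    to ``elephant``) are detected as repeats.  With ``as_list`` the
    repeated tokens themselves are returned, in order.
    """
    per_list = [_perseverations_in(fl.tokens) for fl in dataset.lists]
    if as_list:
        if dataset.hierarchical:
            out: dict[str, list[str]] = {}
            for fl, p in zip(dataset.lists, per_list):
                out.setdefault(fl.subject_id, []).extend(p)
            return pd.Series(out)
        idx = pd.MultiIndex.from_tuples(dataset.listnums, names=["id", "listnum"])
        return pd.Series(per_list, index=idx)
    return dataset.aggregate([float(len(p)) for p in per_list])


def intrusions(
    dataset: FluencyDataset,
    scheme_or_letter: "Scheme | str",
    as_list: bool = False,
):
    """Out-of-category responses per list (or per subject when hierarchical).

    With a semantic scheme, any token not belonging to at least one
    category is an intrusion; with a single target letter, any token not
    beginning with that letter.
    """
    if scheme_or_letter is None:
        raise ValueError("intrusion detection requires a scheme or target letter")
    per_list = [
        remove_intrusions_from_list(fl.tokens, scheme_or_letter)[1]
        for fl in dataset.lists
    ]
    if as_list:
        if dataset.hierarchical:
            out: dict[str, list[str]] = {}
            for fl, p in zip(dataset.lists, per_list):
                out.setdefault(fl.subject_id, []).extend(p)
            return pd.Series(out)
        idx = pd.MultiIndex.from_tuples(dataset.listnums, names=["id", "listnum"])
        return pd.Series(per_list, index=idx)
    return dataset.aggregate([float(len(p)) for p in per_list])


@dataclass(frozen=True)
class NormTable:
    """Word -> numeric norm lookup (frequency, age of acquisition, ...).

    ``missing`` is either a finite substitute value contributed by words
    absent from the table, or ``None`` to ignore such words entirely (they
    never enter the mean).
    """

    values: Mapping[str, float]
    missing: float | None = None

    def __post_init__(self) -> None:
        if self.missing is not None and not math.isfinite(self.missing):
            raise ValueError("missing-value substitute must be finite")

    @classmethod
    def from_csv(cls, path: str | Path, missing: float | None = None) -> "NormTable":
        vals: dict[str, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) < 2:
                    raise ValueError(f"{path}:{lineno}: expected word,value")
                try:
                    vals[row[0].strip().lower()] = float(row[1])
                except ValueError as e:
                    raise ValueError(f"{path}:{lineno}: bad value {row[1]!r}") from e
        return cls(vals, missing)

    def list_mean(self, tokens: Sequence[str]) -> float:
        contrib = []
        for t in tokens:
            if t in self.values:
                contrib.append(self.values[t])
            elif self.missing is not None:
                contrib.append(self.missing)
        if not contrib:
            return float("nan")
        return sum(contrib) / len(contrib)


def word_stat(dataset: FluencyDataset, norms: NormTable) -> pd.Series:
    """Mean norm value over the responses of each list.

    Under the ignore policy a list whose tokens are all absent from the
    table has no defined mean; it is reported as NaN with a warning rather
    than silently zero.
    """
    vals = [norms.list_mean(fl.tokens) for fl in dataset.lists]
    bad = [
        f"{fl.subject_id}/{fl.list_number}"
        for fl, v in zip(dataset.lists, vals)
        if math.isnan(v) and fl.tokens
    ]
    if bad:
        warnings.warn(
            "no norm values found for any token in list(s): " + ", ".join(bad)
        )
    return dataset.aggregate(vals)
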