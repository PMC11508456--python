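"""Combining the univariate and multivariate selections.

Proteoform IDs follow the UniProt convention: a base accession optionally
followed by a dash and an isoform index (``P14618-2`` is isoform 2 of
``P14618``). The merged candidate list is the union of the two selections;
isoform entries are then collapsed to unique base accessions before the
network stage, because interaction and pathway databases track proteins,
not proteoforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class ProteoformID:
    raw: str
    base: str
    isoform_index: int | None

    @property
    def is_isoform(self) -> bool:
        return self.isoform_index is not None


def parse_proteoform(raw: str) -> ProteoformID:
    """Split a proteoform accession into base and optional isoform index."""
    base, dash, suffix = raw.partition("-")
    if not base:
        raise InputError(f"malformed accession {raw!r}: empty base")
    if not dash:
        return ProteoformID(raw=raw, base=base, isoform_index=None)
    if not suffix.isdigit() or int(suffix) < 1:
        raise InputError(f"malformed accession {raw!r}: bad isoform suffix")
    return ProteoformID(raw=raw, base=base, isoform_index=int(suffix))


@dataclass(frozen=True)
class MergeStats:
    """Union of two selections with its inclusion-exclusion bookkeeping."""

    union: frozenset
    n_a: int
    n_b: int
    n_common: int
    n_union: int


def union_with_stats(set_a: Iterable[str], set_b: Iterable[str]) -> MergeStats:
    """Union of two proteoform sets plus |A|, |B|, |A∩B|, |A∪B| counts."""
    a, b = set(set_a), set(set_b)
    u = a | b
    return MergeStats(
        union=frozenset(u),
        n_a=len(a),
        n_b=len(b),
        n_common=len(a & b),
        n_union=len(u),
    )


def collapse_isoforms(proteoforms: Iterable[str]) -> tuple[frozenset, int]:
    """Deduplicate to base accessions; also count isoform entries.

    Returns ``(unique_bases, n_isoform_entries)``. When every isoform's base
    also appears in the input (or collides with another isoform's base),
    ``len(unique_bases) == len(input) - n_isoform_entries``.
    """
    parsed = [parse_proteoform(p) for p in set(proteoforms)]
    bases = frozenset(p.base for p in parsed)
    n_iso = sum(1 for p in parsed if p.is_isoform)
    return bases, n_iso


def inherit_statistics(proteoforms: Iterable[str], stats: pd.DataFrame) -> pd.DataFrame:
    """Per-base statistics table for a collapsed proteoform set.

    Each base accession inherits the log2fc/pvalue/fdr of its most
    significant proteoform (smallest FDR; smallest raw ID on ties, for
    determinism). ``stats`` is the univariate table indexed by raw
    proteoform ID.
    """
    rows = []
    for raw in sorted(set(proteoforms)):
        if raw not in stats.index:
            raise InputError(f"proteoform {raw!r} missing from statistics table")
        pid = parse_proteoform(raw)
        rec = stats.loc[raw]
        rows.append({"base": pid.base, "raw": raw, **rec.to_dict()})
    df = pd.DataFrame(rows)
    df = df.sort_values(["base", "fdr", "raw"], kind="stable")
    out = df.drop_duplicates("base", keep="first").set_index("base")
    return out
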