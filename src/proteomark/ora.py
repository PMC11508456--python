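"""Over-representation analysis against GMT gene-set collections.

For each gene set the overlap with the input protein list is scored with the
upper-tail hypergeometric probability P(X >= k) given the universe size N,
the set size m and the list size n (all intersected with the universe — the
statistical background), followed by Benjamini-Hochberg FDR across sets.
Redundancy among significant sets is reduced with affinity propagation over
Jaccard member-overlap similarities; the exemplars are the representative
pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import AffinityPropagation

from .errors import FormatError, InputError
from .univariate import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    ``sets`` maps set ID to (description, member accessions). Members need
    not all lie in the universe; they are intersected at test time. When no
    universe is supplied it defaults to the union of all members (callers
    add their input list before testing).
    """

    sets: dict[str, tuple[str, frozenset]]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for sid, (_, members) in self.sets.items():
            if not members:
                raise InputError(f"gene set {sid!r} is empty")
        if not self.universe:
            u: set = set()
            for _, members in self.sets.values():
                u |= members
            self.universe = frozenset(u)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line — ID, description, members."""
    sets: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"line {lineno}: GMT needs >= 3 tab-separated fields")
            sets[cols[0]] = (cols[1], frozenset(c for c in cols[2:] if c))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in collection.sets.items():
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def fisher_ora(
    input_list: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of a list against each set.

    Returns a DataFrame (one row per set, sorted by FDR then p) with the
    overlap count k, the within-universe set size m, list size n, universe
    size N, the enrichment ratio (k/n)/(m/N), the one-sided p-value
    P(X >= k), and the BH FDR across all tested sets.
    """
    uni = frozenset(universe) if universe is not None else collection.universe | set(input_list)
    hits = set(input_list) & uni
    if not hits:
        raise InputError("input list does not intersect the universe")
    n, N = len(hits), len(uni)
    rows = []
    for sid, (desc, members) in collection.sets.items():
        m = len(members & uni)
        k = len(members & hits)
        if m == 0:
            p, ratio = 1.0, float("nan")
        else:
            p = float(hypergeom.sf(k - 1, N, m, n))
            ratio = (k / n) / (m / N)
        rows.append(
            {"set_id": sid, "description": desc, "k": k, "m": m, "n": n, "N": N,
             "enrichment_ratio": ratio, "pvalue": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    df = df.sort_values(["fdr", "pvalue", "set_id"], kind="stable").reset_index(drop=True)
    return df


def _jaccard_matrix(member_sets: list[frozenset]) -> np.ndarray:
    k = len(member_sets)
    S = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = member_sets[i], member_sets[j]
            union = len(a | b)
            S[i, j] = S[j, i] = len(a & b) / union if union else 0.0
    return S


def affinity_propagation_reduce(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    fdr_cutoff: float = 0.05,
    damping: float = 0.5,
    preference: float | None = None,
    max_iter: int = 500,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Flag exemplar sets among the significant ORA results.

    Affinity propagation clusters the significant sets (FDR <= cutoff) on
    the Jaccard similarity of their within-universe members; each cluster's
    exemplar represents its redundant group. Deterministic for fixed
    damping/preference (preference defaults to the median similarity). If
    message passing fails to converge, every significant set is flagged as
    its own exemplar and a warning is raised.

    Returns a copy of ``results`` with ``is_exemplar`` and ``exemplar_of``
    columns (NaN outside the significant subset).
    """
    out = results.copy()
    out["is_exemplar"] = False
    out["exemplar_of"] = pd.NA
    sig_idx = out.index[out["fdr"] <= fdr_cutoff].tolist()
    if not sig_idx:
        raise InputError("no significant sets at the given FDR cutoff")
    uni = frozenset(universe) if universe is not None else collection.universe
    member_sets = [collection.sets[out.loc[i, "set_id"]][1] & uni for i in sig_idx]
    ids = [out.loc[i, "set_id"] for i in sig_idx]

    if len(sig_idx) == 1:
        out.loc[sig_idx[0], ["is_exemplar", "exemplar_of"]] = [True, ids[0]]
        return out

    S = _jaccard_matrix(member_sets)
    off_diag = S[~np.eye(len(S), dtype=bool)]
    if np.all(off_diag == 0):
        # pairwise-disjoint sets: nothing to merge, AP is ill-posed here
        for i, sid in zip(sig_idx, ids):
            out.loc[i, ["is_exemplar", "exemplar_of"]] = [True, sid]
        return out

    pref = float(np.median(S)) if preference is None else preference
    ap = AffinityPropagation(
        affinity="precomputed", damping=damping, preference=pref,
        max_iter=max_iter, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence handled explicitly below
        labels = ap.fit_predict(S)
    centers = getattr(ap, "cluster_centers_indices_", None)
    if centers is None or len(np.atleast_1d(centers)) == 0 or (labels < 0).any():
        warnings.warn(
            "affinity propagation did not converge; flagging all significant sets",
            RuntimeWarning,
            stacklevel=2,
        )
        for i, sid in zip(sig_idx, ids):
            out.loc[i, ["is_exemplar", "exemplar_of"]] = [True, sid]
        return out
    for pos, (i, lab) in enumerate(zip(sig_idx, labels)):
        exemplar = ids[int(centers[lab])]
        out.loc[i, "exemplar_of"] = exemplar
        out.loc[i, "is_exemplar"] = pos == int(centers[lab])
    return out
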