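"""Synthetic data with the statistical structure the pipeline assumes.

Generates (a) a nonnegative label-free abundance matrix — log-normal
intensities with block-correlated noise (protein communities), planted
differential proteoforms of configurable log2 effect, UniProt-style isoform
rows and optional zero-encoded missingness; (b) a MITAB interactome with
planted marker-marker edges plus the artefacts the network filters must
handle (duplicate rows, self-loops, non-human decoy rows, non-protein
interactor types); and (c) a GMT gene-set collection with one set enriched
for the planted markers.

Defaults mirror a salivary biomarker cohort: 10 cases vs 20 controls,
2815 proteoforms, ~5% of them truly differential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .matrix import CASE, CONTROL, AbundanceMatrix
from .ora import GeneSetCollection


@dataclass
class SyntheticConfig:
    """Parameters of the abundance-matrix generator.

    ``n_markers`` defaults to 5% of ``n_proteins``. ``effect_log2fc`` is the
    planted group-mean difference on the log2 scale (sign drawn per marker).
    ``block_size``/``block_rho`` define equicorrelated noise communities;
    ``noise_sd`` is the residual SD on the log2 scale; ``isoform_fraction``
    of the rows are dash-suffixed isoforms of other rows; ``missing_rate``
    zeroes entries at random (non-detection).
    """

    n_cases: int = 10
    n_controls: int = 20
    n_proteins: int = 2815
    n_markers: int | None = None
    effect_log2fc: float = 2.0
    block_size: int = 50
    block_rho: float = 0.5
    isoform_fraction: float = 0.10
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_markers is None:
            self.n_markers = round(0.05 * self.n_proteins)
        checks = [
            ("n_cases", self.n_cases >= 2),
            ("n_controls", self.n_controls >= 2),
            ("n_proteins", self.n_proteins >= 1),
            ("n_markers", 0 <= self.n_markers <= self.n_proteins),
            ("effect_log2fc", self.effect_log2fc >= 0),
            ("block_size", self.block_size >= 1),
            ("block_rho", 0 <= self.block_rho < 1),
            ("isoform_fraction", 0 <= self.isoform_fraction <= 1),
            ("noise_sd", self.noise_sd > 0),
            ("missing_rate", 0 <= self.missing_rate < 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ParameterError(f"invalid value for {name}: {getattr(self, name)!r}")


@dataclass
class GroundTruth:
    """What was planted: marker IDs and directions, interactome edges, and
    the ID of the marker-enriched gene set."""

    marker_ids: frozenset
    direction: dict[str, str]  # proteoform -> "up" | "down"
    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    planted_set_id: str = "SET_PLANTED"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_ids": sorted(self.marker_ids),
            "direction": self.direction,
            "planted_edges": [list(e) for e in self.planted_edges],
            "planted_set_id": self.planted_set_id,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            marker_ids=frozenset(d["marker_ids"]),
            direction=dict(d["direction"]),
            planted_edges=[tuple(e) for e in d["planted_edges"]],
            planted_set_id=d["planted_set_id"],
        )


def _make_row_ids(n_proteins: int, isoform_fraction: float, rng: np.random.Generator) -> list[str]:
    """Accession list: bases 'P00001'... plus dash-suffixed isoform rows.

    Exactly round(isoform_fraction * n_proteins) rows are isoforms whose
    base accession belongs to another generated row.
    """
    n_iso = round(isoform_fraction * n_proteins)
    n_base = n_proteins - n_iso
    if n_base < 1 and n_iso > 0:
        raise ParameterError("isoform_fraction leaves no base accessions")
    bases = [f"P{i + 1:05d}" for i in range(n_base)]
    next_suffix = {b: 2 for b in bases}
    iso_ids = []
    if n_iso:
        parents = rng.choice(n_base, size=n_iso, replace=True)
        for pi in parents:
            b = bases[pi]
            iso_ids.append(f"{b}-{next_suffix[b]}")
            next_suffix[b] += 1
    ids = bases + iso_ids
    order = rng.permutation(n_proteins)
    return [ids[i] for i in order]


def generate_abundance(config: SyntheticConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Draw an abundance matrix plus its ground truth.

    Log2 abundances are Gaussian around a per-protein baseline, with
    equicorrelated block noise; planted markers get a +/-effect_log2fc shift
    in the case group; values are exponentiated to the nonnegative raw scale
    and a ``missing_rate`` fraction is zeroed. Identical config and seed
    give byte-identical TSV output.
    """
    rng = np.random.default_rng(config.seed)
    p, n = config.n_proteins, config.n_cases + config.n_controls
    ids = _make_row_ids(p, config.isoform_fraction, rng)
    sample_ids = [f"case_{i + 1:02d}" for i in range(config.n_cases)] + [
        f"ctrl_{i + 1:02d}" for i in range(config.n_controls)
    ]
    groups = pd.Series(
        [CASE] * config.n_cases + [CONTROL] * config.n_controls, index=sample_ids
    )

    baseline = rng.uniform(10.0, 25.0, size=p)  # log2 intensity scale
    block_of = np.arange(p) // config.block_size
    n_blocks = int(block_of.max()) + 1
    shared = rng.standard_normal((n_blocks, n))
    resid = rng.standard_normal((p, n))
    rho = config.block_rho
    noise = config.noise_sd * (
        np.sqrt(rho) * shared[block_of] + np.sqrt(1.0 - rho) * resid
    )

    marker_pos = rng.choice(p, size=config.n_markers, replace=False)
    signs = rng.choice([1.0, -1.0], size=config.n_markers)
    effect = np.zeros(p)
    effect[marker_pos] = signs * config.effect_log2fc
    is_case = np.array([g == CASE for g in groups])

    log2x = baseline[:, None] + noise + np.outer(effect, is_case.astype(float))
    values = np.exp2(log2x)
    if config.missing_rate > 0:
        values[rng.random((p, n)) < config.missing_rate] = 0.0

    matrix = AbundanceMatrix(pd.DataFrame(values, index=ids, columns=sample_ids), groups)

    marker_ids = [ids[i] for i in marker_pos]
    direction = {
        mid: ("up" if s > 0 else "down") for mid, s in zip(marker_ids, signs)
    }
    # plant a path through the markers so the pruned network is connected
    shuffled = [marker_ids[i] for i in rng.permutation(len(marker_ids))]
    planted_edges = [
        (shuffled[i], shuffled[i + 1]) for i in range(len(shuffled) - 1)
    ]
    truth = GroundTruth(
        marker_ids=frozenset(marker_ids),
        direction=direction,
        planted_edges=planted_edges,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# interactome (MITAB)
# ---------------------------------------------------------------------------

_MITAB_NCOLS = 36
_HUMAN = "taxid:9606(Homo sapiens)"
_PROTEIN = 'psi-mi:"MI:0326"(protein)'
_RNA = 'psi-mi:"MI:0320"(ribonucleic acid)'


def _mitab_line(
    id_a: str,
    id_b: str,
    taxid: str = _HUMAN,
    type_a: str = _PROTEIN,
    type_b: str = _PROTEIN,
    interaction_index: int = 0,
) -> str:
    cols = ["-"] * _MITAB_NCOLS
    cols[0] = f"uniprotkb:{id_a}"
    cols[1] = f"uniprotkb:{id_b}"
    cols[6] = 'psi-mi:"MI:0004"(affinity chromatography technology)'
    cols[8] = "pubmed:10000000"
    cols[9] = taxid
    cols[10] = taxid
    cols[11] = 'psi-mi:"MI:0915"(physical association)'
    cols[12] = 'psi-mi:"MI:0471"(MINT)'
    cols[13] = f"synthetic:INT-{interaction_index:06d}"
    cols[14] = "score:0.5"
    cols[20] = type_a
    cols[21] = type_b
    return "\t".join(cols)


def generate_interactome(
    truth: GroundTruth,
    universe: Sequence[str],
    path: str | Path,
    background_edge_prob: float = 0.0005,
    seed: int = 0,
    decoy_taxid_fraction: float = 0.1,
    duplicate_fraction: float = 0.05,
    n_self_loops: int = 5,
    nonprotein_fraction: float = 0.02,
) -> dict:
    """Write a synthetic MITAB interactome; returns per-category row counts.

    Rows comprise the planted marker-marker edges (guaranteed present),
    Bernoulli background edges over the universe, duplicated rows (some with
    swapped interactor order), self-loops, non-human decoy rows (taxid
    10090) and non-protein-type decoys — the artefacts the taxonomy/type
    filters and the pruning step must remove.
    """
    universe = list(universe)
    if not universe:
        raise InputError("universe must be non-empty")
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = list(truth.planted_edges)
    n_planted = len(edges)

    n_background = 0
    if background_edge_prob > 0 and len(universe) > 1:
        u = len(universe)
        n_pairs = u * (u - 1) // 2
        n_background = int(rng.binomial(min(n_pairs, 2**31 - 1), background_edge_prob))
        for _ in range(n_background):
            i, j = rng.choice(u, size=2, replace=False)
            edges.append((universe[i], universe[j]))

    lines = []
    counts = {"planted": n_planted, "background": n_background}
    idx = 0
    for a, b in edges:
        lines.append(_mitab_line(a, b, interaction_index=idx))
        idx += 1
    # duplicates: re-emit a fraction of real edges, half with swapped order
    n_dup = round(duplicate_fraction * len(edges))
    counts["duplicates"] = n_dup
    if n_dup:
        for pos in rng.choice(len(edges), size=n_dup, replace=True):
            a, b = edges[pos]
            if rng.random() < 0.5:
                a, b = b, a
            lines.append(_mitab_line(a, b, interaction_index=idx))
            idx += 1
    counts["self_loops"] = n_self_loops
    for _ in range(n_self_loops):
        a = universe[int(rng.integers(len(universe)))]
        lines.append(_mitab_line(a, a, interaction_index=idx))
        idx += 1
    # decoys scale with the number of genuine rows
    n_real = len(lines)
    n_decoy_tax = round(decoy_taxid_fraction * n_real)
    counts["decoy_taxid"] = n_decoy_tax
    for _ in range(n_decoy_tax):
        i, j = rng.integers(len(universe)), rng.integers(len(universe))
        lines.append(
            _mitab_line(universe[int(i)], universe[int(j)],
                        taxid="taxid:10090(Mus musculus)", interaction_index=idx)
        )
        idx += 1
    n_decoy_type = round(nonprotein_fraction * n_real)
    counts["decoy_type"] = n_decoy_type
    for _ in range(n_decoy_type):
        i, j = rng.integers(len(universe)), rng.integers(len(universe))
        lines.append(
            _mitab_line(universe[int(i)], universe[int(j)],
                        type_b=_RNA, interaction_index=idx)
        )
        idx += 1
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    counts["total"] = len(lines)
    return counts


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def generate_gene_sets(
    truth: GroundTruth,
    universe: Sequence[str],
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 100),
    seed: int = 0,
    marker_fraction: float = 0.8,
) -> GeneSetCollection:
    """Random gene sets plus one set enriched for the planted markers.

    The planted set (ID ``truth.planted_set_id``) draws ``marker_fraction``
    of its members from the markers present in the universe, the rest
    uniformly; the remaining ``n_sets - 1`` sets are uniform draws.
    """
    universe = list(dict.fromkeys(universe))
    if n_sets < 1:
        raise ParameterError("n_sets must be >= 1")
    lo, hi = set_size_range
    if not 1 <= lo <= hi:
        raise ParameterError("set_size_range must satisfy 1 <= lo <= hi")
    if hi > len(universe):
        raise InputError(
            f"set size {hi} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    sets: dict[str, tuple[str, frozenset]] = {}

    markers_in_uni = sorted(set(truth.marker_ids) & set(universe))
    size = int(rng.integers(lo, hi + 1))
    n_mark = min(round(marker_fraction * size), len(markers_in_uni))
    members = set(
        rng.choice(markers_in_uni, size=n_mark, replace=False)
    ) if n_mark else set()
    others = [u for u in universe if u not in members]
    n_fill = min(size - len(members), len(others))
    if n_fill > 0:
        members |= set(rng.choice(others, size=n_fill, replace=False))
    if not members:
        members = {universe[0]}
    sets[truth.planted_set_id] = ("planted marker-enriched set", frozenset(members))

    for s in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(universe, size=size, replace=False))
        sets[f"SET_{s + 1:04d}"] = (f"random set {s + 1}", members)
    return GeneSetCollection(sets=sets, universe=frozenset(universe))


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
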