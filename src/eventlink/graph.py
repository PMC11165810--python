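"""Entity vocabulary, event nodes, heterogeneous graph, features and edge splits.

The core modelling object is the *event node*: a drug-target pair together with
the set of diseases that pair treats, Q = <drug, target, Z>.  Events are derived
from three pairwise association tables (drug-target, drug-disease,
target-disease) by intersecting the drug's diseases with the target's diseases.
Events and diseases then form a bipartite heterogeneous graph whose
event-disease "link" edges are the objects of prediction.

Input tables use the two-column tab-separated dialect of biomedical edge-list
releases: UTF-8, one pair per line, lines starting with ``#`` ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

RELATION_KINDS = ("drug-target", "drug-disease", "target-disease")


class ParseError(ValueError):
    """Raised for a malformed edge-list line; names the file and line number."""


@dataclass(frozen=True)
class PairTable:
    """A deduplicated pairwise relation table (order of first appearance kept)."""

    relation_kind: str
    rows: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if self.relation_kind not in RELATION_KINDS:
            raise ValueError(f"unknown relation kind {self.relation_kind!r}")

    def __len__(self) -> int:
        return len(self.rows)

    @staticmethod
    def from_rows(relation_kind: str, rows) -> "PairTable":
        seen: dict[tuple[str, str], None] = {}
        for r in rows:
            seen[(str(r[0]), str(r[1]))] = None
        return PairTable(relation_kind, tuple(seen))


@dataclass(frozen=True)
class EntityVocab:
    """Ordered drug / target / disease identifier universes with 0-based indices."""

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    drug_index: dict[str, int] = field(repr=False, default_factory=dict)
    target_index: dict[str, int] = field(repr=False, default_factory=dict)
    disease_index: dict[str, int] = field(repr=False, default_factory=dict)

    @staticmethod
    def from_ids(drugs, targets, diseases) -> "EntityVocab":
        d, t, z = sorted(set(drugs)), sorted(set(targets)), sorted(set(diseases))
        return EntityVocab(
            tuple(d), tuple(t), tuple(z),
            {s: i for i, s in enumerate(d)},
            {s: i for i, s in enumerate(t)},
            {s: i for i, s in enumerate(z)},
        )

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


@dataclass(frozen=True)
class EventNode:
    """Ternary unit Q = <drug, target, disease set>; Z is non-empty."""

    drug_index: int
    target_index: int
    diseases: frozenset[int]

    def __post_init__(self):
        if not self.diseases:
            raise ValueError("event requires a non-empty disease set")


@dataclass(frozen=True)
class HeteroGraph:
    """Bipartite event-disease graph; drug/target are event annotations."""

    n_events: int
    n_diseases: int
    edges: tuple[tuple[int, int], ...]        # (event_index, disease_index), sorted
    event_annotations: tuple[tuple[int, int], ...]  # (drug_index, target_index)

    def __post_init__(self):
        es = set(self.edges)
        if len(es) != len(self.edges):
            raise ValueError("duplicate edges")
        for u, v in self.edges:
            if not (0 <= u < self.n_events and 0 <= v < self.n_diseases):
                raise ValueError(f"edge ({u},{v}) out of range")

    @property
    def edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.edges)


@dataclass
class EdgeSplit:
    """60/10/30-style positive partition plus per-split sampled negatives."""

    train_pos: tuple[tuple[int, int], ...]
    val_pos: tuple[tuple[int, int], ...]
    test_pos: tuple[tuple[int, int], ...]
    train_neg: tuple[tuple[int, int], ...] = ()
    val_neg: tuple[tuple[int, int], ...] = ()
    test_neg: tuple[tuple[int, int], ...] = ()
    seed: int = 0


# ---------------------------------------------------------------------------
# loading


def _parse_edge_list(path: str | Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rows.append((parts[0].strip(), parts[1].strip()))
    return rows


def load_pair_tables(dt_path, dd_path, td_path) -> tuple[EntityVocab, PairTable, PairTable, PairTable]:
    """Read the three edge lists, deduplicate, and build the shared vocabulary.

    Identifier order in the vocabulary is lexicographic, which fixes every
    downstream index deterministically.
    """
    dt = PairTable.from_rows("drug-target", _parse_edge_list(dt_path))
    dd = PairTable.from_rows("drug-disease", _parse_edge_list(dd_path))
    td = PairTable.from_rows("target-disease", _parse_edge_list(td_path))
    vocab = vocab_from_tables(dt, dd, td)
    for tab in (dt, dd, td):
        logger.info("loaded %s: %d unique pairs", tab.relation_kind, len(tab))
    return vocab, dt, dd, td


def vocab_from_tables(dt: PairTable, dd: PairTable, td: PairTable) -> EntityVocab:
    drugs = [r[0] for r in dt.rows] + [r[0] for r in dd.rows]
    targets = [r[1] for r in dt.rows] + [r[0] for r in td.rows]
    diseases = [r[1] for r in dd.rows] + [r[1] for r in td.rows]
    return EntityVocab.from_ids(drugs, targets, diseases)


def write_pair_table(table: PairTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# {table.relation_kind}\n")
        for a, b in table.rows:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# events and graph


def build_events(dt: PairTable, dd: PairTable, td: PairTable,
                 vocab: EntityVocab | None = None) -> list[EventNode]:
    """One event per drug-target pair whose treated-disease intersection is non-empty.

    Z(X, Y) = {z : (X, z) in drug-disease and (Y, z) in target-disease}; pairs
    with empty Z are dropped.  Output is ordered by (drug index, target index).
    """
    if vocab is None:
        vocab = vocab_from_tables(dt, dd, td)
    drug_dis: dict[int, set[int]] = {}
    for x, z in dd.rows:
        drug_dis.setdefault(vocab.drug_index[x], set()).add(vocab.disease_index[z])
    targ_dis: dict[int, set[int]] = {}
    for y, z in td.rows:
        targ_dis.setdefault(vocab.target_index[y], set()).add(vocab.disease_index[z])

    events: list[EventNode] = []
    pairs = sorted({(vocab.drug_index[x], vocab.target_index[y]) for x, y in dt.rows})
    for xi, yi in pairs:
        z = drug_dis.get(xi, set()) & targ_dis.get(yi, set())
        if z:
            events.append(EventNode(xi, yi, frozenset(z)))
    return events


def build_hetero_graph(events: list[EventNode], n_diseases: int) -> HeteroGraph:
    """Edge (i, j) for every disease j in event i's treated set.

    Diseases that no event links to are kept as isolated nodes so column
    indices stay stable.
    """
    if not events:
        raise ValueError("no events")
    edges = sorted((i, j) for i, ev in enumerate(events) for j in sorted(ev.diseases))
    ann = tuple((ev.drug_index, ev.target_index) for ev in events)
    return HeteroGraph(len(events), n_diseases, tuple(edges), ann)


def build_event_features(events: list[EventNode], n_diseases: int) -> np.ndarray:
    """One-hot association matrix A (q x z): A[i, j] = 1 iff event i treats disease j."""
    A = np.zeros((len(events), n_diseases), dtype=np.float64)
    for i, ev in enumerate(events):
        A[i, sorted(ev.diseases)] = 1.0
    return A


def init_disease_features(n_diseases: int, dim: int, seed: int) -> np.ndarray:
    """Random i.i.d. standard-normal disease features, reproducible under seed."""
    if dim <= 0:
        raise ValueError("feature dimension must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_diseases, dim))


# ---------------------------------------------------------------------------
# splits and negatives


def split_edges(graph: HeteroGraph, ratios=(0.6, 0.1, 0.3), seed: int = 0) -> EdgeSplit:
    """Uniform random 60/10/30 partition of positive edges (negatives left empty)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    n = len(graph.edges)
    if n < 10:
        raise ValueError("graph must have at least 10 edges to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    c1 = int(np.floor(ratios[0] * n))
    c2 = int(np.floor((ratios[0] + ratios[1]) * n))
    edges = np.asarray(graph.edges)
    take = lambda idx: tuple(map(tuple, edges[idx].tolist()))
    return EdgeSplit(
        train_pos=take(perm[:c1]),
        val_pos=take(perm[c1:c2]),
        test_pos=take(perm[c2:]),
        seed=seed,
    )


def sample_negative_edges(graph: HeteroGraph, n: int, seed: int,
                          exclude: set[tuple[int, int]] | frozenset = frozenset()) -> tuple[tuple[int, int], ...]:
    """Draw n distinct non-edges uniformly without replacement.

    Excludes every observed edge plus `exclude`.  The full candidate complement
    is enumerated (desk scale: q*z pairs fit in memory).
    """
    forbidden = np.zeros((graph.n_events, graph.n_diseases), dtype=bool)
    for u, v in graph.edges:
        forbidden[u, v] = True
    for u, v in exclude:
        forbidden[u, v] = True
    flat = np.flatnonzero(~forbidden.ravel())
    if n > flat.size:
        raise ValueError(
            f"graph too dense for requested negatives: {n} asked, {flat.size} non-edges available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    z = graph.n_diseases
    return tuple(sorted((int(c) // z, int(c) % z) for c in chosen))


def attach_negatives(graph: HeteroGraph, split: EdgeSplit, ratio: float = 1.0,
                     seed: int | None = None) -> EdgeSplit:
    """Sample per-split negatives (ratio x positives), mutually disjoint across splits."""
    seed = split.seed if seed is None else seed
    taken: set[tuple[int, int]] = set()
    out = []
    for k, pos in enumerate((split.train_pos, split.val_pos, split.test_pos)):
        neg = sample_negative_edges(graph, int(round(ratio * len(pos))), seed + k, exclude=taken)
        taken.update(neg)
        out.append(neg)
    return EdgeSplit(split.train_pos, split.val_pos, split.test_pos,
                     out[0], out[1], out[2], seed=split.seed)


# ---------------------------------------------------------------------------
# serialization


def save_graph(graph: HeteroGraph, events: list[EventNode], vocab: EntityVocab,
               outdir: str | Path) -> dict:
    """Write events.tsv, edges.tsv, vocab.tsv and a JSON count summary; return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with (outdir / "events.tsv").open("w", encoding="utf-8") as fh:
        fh.write("event_id\tdrug_id\ttarget_id\n")
        for i, ev in enumerate(events):
            fh.write(f"{i}\t{vocab.drug_ids[ev.drug_index]}\t{vocab.target_ids[ev.target_index]}\n")
    with (outdir / "edges.tsv").open("w", encoding="utf-8") as fh:
        fh.write("event_id\tdisease_id\n")
        for u, v in graph.edges:
            fh.write(f"{u}\t{vocab.disease_ids[v]}\n")
    with (outdir / "vocab.tsv").open("w", encoding="utf-8") as fh:
        fh.write("namespace\tidentifier\tindex\n")
        for ns, ids in (("drug", vocab.drug_ids), ("target", vocab.target_ids),
                        ("disease", vocab.disease_ids)):
            for i, s in enumerate(ids):
                fh.write(f"{ns}\t{s}\t{i}\n")
    summary = {
        "n_drugs": vocab.n_drugs,
        "n_targets": vocab.n_targets,
        "n_diseases": vocab.n_diseases,
        "n_events": graph.n_events,
        "n_edges": len(graph.edges),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
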