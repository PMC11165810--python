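"""Planted-cluster generator for drug-target-disease pair tables.

Real drug/target/disease association releases are not redistributable at desk
scale, so testing and benchmarking use a stochastic block construction: drugs,
targets and diseases are assigned uniformly to latent clusters; a drug-target
pair forms within its cluster with probability ``p_dt`` (and at ``0.05 * p_dt``
across clusters); drug-disease and target-disease associations are Bernoulli
with probability ``p_within`` inside the cluster and ``p_between`` outside.
Events derived from these tables therefore treat cluster-coherent disease
sets, so held-out event-disease links carry a learnable signal whose strength
is controlled by ``p_within / p_between``.

Defaults are the benchmark condition used throughout the package: a
60-drug / 40-target / 120-disease universe with 4 clusters and a strong
contrast (0.9 vs 0.02).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import EntityVocab, PairTable, vocab_from_tables

__all__ = ["SyntheticConfig", "generate", "make_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 60
    n_targets: int = 40
    n_diseases: int = 120
    n_clusters: int = 4
    p_within: float = 0.9
    p_between: float = 0.02
    p_dt: float = 0.3
    cross_dt_factor: float = 0.05   # cross-cluster drug-target rate = factor * p_dt
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_within", "p_between", "p_dt"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        positive = [n for n in (self.n_drugs, self.n_targets, self.n_diseases) if n > 0]
        if positive and min(positive) < self.n_clusters:
            raise ValueError("every non-empty entity universe needs >= n_clusters members")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate(config: SyntheticConfig) -> tuple[PairTable, PairTable, PairTable, dict[str, int]]:
    """Draw the three pair tables; returns them plus the ground-truth cluster map.

    The cluster map sends every entity identifier (drug, target or disease) to
    its latent cluster.  Fully reproducible under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    drugs = _ids("D", config.n_drugs)
    targets = _ids("T", config.n_targets)
    diseases = _ids("Z", config.n_diseases)

    c_drug = rng.integers(0, config.n_clusters, size=config.n_drugs)
    c_targ = rng.integers(0, config.n_clusters, size=config.n_targets)
    c_dis = rng.integers(0, config.n_clusters, size=config.n_diseases)

    def block_sample(rows, row_c, cols, col_c, p_in, p_out):
        if not rows or not cols:
            return []
        same = row_c[:, None] == col_c[None, :]
        p = np.where(same, p_in, p_out)
        draw = rng.random(p.shape) < p
        return [(rows[i], cols[j]) for i, j in zip(*np.nonzero(draw))]

    dt_rows = block_sample(drugs, c_drug, targets, c_targ,
                           config.p_dt, config.cross_dt_factor * config.p_dt)
    dd_rows = block_sample(drugs, c_drug, diseases, c_dis,
                           config.p_within, config.p_between)
    td_rows = block_sample(targets, c_targ, diseases, c_dis,
                           config.p_within, config.p_between)

    clusters: dict[str, int] = {}
    for ids, cs in ((drugs, c_drug), (targets, c_targ), (diseases, c_dis)):
        clusters.update({s: int(c) for s, c in zip(ids, cs)})

    return (
        PairTable.from_rows("drug-target", dt_rows),
        PairTable.from_rows("drug-disease", dd_rows),
        PairTable.from_rows("target-disease", td_rows),
        clusters,
    )


def make_fixture() -> tuple[EntityVocab, PairTable, PairTable, PairTable]:
    """Tiny deterministic 3-drug / 3-target / 6-disease dataset.

    Drug X1 paired with target Y1 treats {Z1, Z2, Zz}; two further pairs cover
    the remaining diseases, with Z2 shared between two events.  Used throughout
    the unit tests and the documentation examples.
    """
    dt = PairTable.from_rows("drug-target", [("X1", "Y1"), ("X2", "Y2"), ("X3", "Y3")])
    dd = PairTable.from_rows("drug-disease", [
        ("X1", "Z1"), ("X1", "Z2"), ("X1", "Zz"),
        ("X2", "Z2"), ("X2", "Z3"),
        ("X3", "Z4"), ("X3", "Z5"),
    ])
    td = PairTable.from_rows("target-disease", [
        ("Y1", "Z1"), ("Y1", "Z2"), ("Y1", "Zz"),
        ("Y2", "Z2"), ("Y2", "Z3"),
        ("Y3", "Z4"), ("Y3", "Z5"),
    ])
    return vocab_from_tables(dt, dd, td), dt, dd, td


def write_cluster_sidecar(clusters: dict[str, int], path) -> None:
    """Ground-truth clusters as a two-column TSV (identifier, cluster)."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("identifier\tcluster\n")
        for k in sorted(clusters):
            fh.write(f"{k}\t{clusters[k]}\n")
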