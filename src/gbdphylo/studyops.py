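"""Settings-grid evaluation, Pareto selection and host-specificity summaries.

Each grid point is scored by six objectives: taxon support and clustering
agreement (MRI) at the species, genus and family ranks.  The selection is a
two-step Pareto filter per sequence type: first the non-dominated set on the
three taxon-support objectives, then, within it, the non-dominated set on
the three MRI objectives.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import AMINO_ACID, NUCLEOTIDE
from .errors import UsageError
from .gbdp import ALGORITHMS, ALL_FORMULAS, CORE_FORMULAS, EVALUE_GRID, GBDPSettings

logger = logging.getLogger(__name__)

OBJECTIVE_RANKS = ("species", "genus", "family")


@dataclass
class SettingsScore:
    """Six objective values for one grid point."""

    settings: GBDPSettings
    taxon_support: dict[str, float]
    mri: dict[str, float]

    def objectives(self) -> dict[str, float]:
        out = {f"taxon_support_{r}": self.taxon_support[r] for r in OBJECTIVE_RANKS}
        out.update({f"mri_{r}": self.mri[r] for r in OBJECTIVE_RANKS})
        if len(out) != 6:
            raise UsageError("expected exactly six objective values")
        return out


@dataclass(frozen=True)
class HostSpecificity:
    """Berger-Parker style specificity of one cluster: modal host share m/N."""

    cluster: str
    n_hosts: int
    modal_count: int
    modal_host: str

    @property
    def index(self) -> float:
        return self.modal_count / self.n_hosts


def settings_grid(
    all_formulas: bool = False,
    n_replicates: int = 100,
    seed: int = 0,
) -> list[GBDPSettings]:
    """Full Cartesian settings grid in deterministic order
    (seq_type, e-value, algorithm, formula): 72 points with the three
    normative formulas, 240 with all ten registry slots enabled."""
    formulas = ALL_FORMULAS if all_formulas else CORE_FORMULAS
    grid = []
    for seq_type in (NUCLEOTIDE, AMINO_ACID):
        for evalue in EVALUE_GRID:
            for algorithm in ALGORITHMS:
                for formula in formulas:
                    grid.append(
                        GBDPSettings(
                            seq_type=seq_type,
                            evalue_max=evalue,
                            algorithm=algorithm,
                            formula=formula,
                            n_replicates=n_replicates,
                            seed=seed,
                        )
                    )
    return grid


def _dominates(p: Mapping[str, float], q: Mapping[str, float], objectives) -> bool:
    ge = all(p[o] >= q[o] for o in objectives)
    gt = any(p[o] > q[o] for o in objectives)
    return ge and gt


def pareto_front(points: Sequence, objectives: Sequence[str], values=None) -> list:
    """Non-dominated subset (maximization), input order preserved.

    ``points`` may be any objects; ``values`` maps a point to its objective
    dict (defaults to treating points as mappings themselves).
    """
    if values is None:
        values = lambda p: p
    vals = [values(p) for p in points]
    keep = []
    for i, p in enumerate(points):
        if not any(
            _dominates(vals[j], vals[i], objectives)
            for j in range(len(points))
            if j != i
        ):
            keep.append(p)
    return keep


def two_step_selection(scores: Sequence[SettingsScore]) -> list[SettingsScore]:
    """Per sequence type: Pareto front on the three taxon-support objectives,
    then, within that subset, the front on the three MRI objectives."""
    ts_objs = [f"taxon_support_{r}" for r in OBJECTIVE_RANKS]
    mri_objs = [f"mri_{r}" for r in OBJECTIVE_RANKS]
    out: list[SettingsScore] = []
    for seq_type in (NUCLEOTIDE, AMINO_ACID):
        group = [s for s in scores if s.settings.seq_type == seq_type]
        step1 = pareto_front(group, ts_objs, values=lambda s: s.objectives())
        step2 = pareto_front(step1, mri_objs, values=lambda s: s.objectives())
        out.extend(step2)
    return out


def scores_frame(scores: Sequence[SettingsScore]) -> pd.DataFrame:
    """Grid-evaluation report with per-sequence-type Pareto selection flags."""
    selected = {id(s) for s in two_step_selection(scores)}
    rows = []
    for s in scores:
        row = dict(
            seq_type=s.settings.seq_type,
            evalue=s.settings.evalue_max,
            algorithm=s.settings.algorithm,
            formula=s.settings.formula,
        )
        row.update(s.objectives())
        row["selected"] = id(s) in selected
        rows.append(row)
    return pd.DataFrame(rows)


def _standardize_host(name: str, host_rank: str) -> str | None:
    tokens = [t for t in str(name).split() if any(c.isalpha() for c in t)]
    if not tokens:
        return None
    if host_rank == "genus":
        return tokens[0]
    return " ".join(tokens[:2])


def host_specificity(
    partition: Mapping,
    host_table: pd.DataFrame,
    host_rank: str = "species",
) -> list[HostSpecificity]:
    """Per-cluster modal-host share m/N.

    N counts the cluster's genomes with a non-empty host entry; m is the
    count of the most frequent (standardized) host name.  Host names are
    "Genus species" binomials; at genus rank only the first token is used.
    Clusters without any host annotation are omitted; malformed host strings
    are skipped with a warning.
    """
    if host_rank not in ("species", "genus"):
        raise UsageError(f"unsupported host rank {host_rank!r}")
    hosts = host_table.set_index("genome_id")["host"].to_dict()
    per_cluster: dict[str, list[str]] = {}
    for genome, cluster in partition.items():
        raw = hosts.get(genome, "")
        if not raw:
            continue
        std = _standardize_host(raw, host_rank)
        if std is None:
            logger.warning("skipping malformed host entry %r for %s", raw, genome)
            continue
        per_cluster.setdefault(cluster, []).append(std)
    out = []
    for cluster in sorted(per_cluster, key=str):
        names = per_cluster[cluster]
        counts: dict[str, int] = {}
        for nm in names:
            counts[nm] = counts.get(nm, 0) + 1
        m = max(counts.values())
        modal = min(nm for nm, c in counts.items() if c == m)
        out.append(
            HostSpecificity(
                cluster=str(cluster), n_hosts=len(names), modal_count=m,
                modal_host=modal,
            )
        )
    return out


def host_specificity_frame(records: Sequence[HostSpecificity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                cluster=r.cluster, N=r.n_hosts, m=r.modal_count,
                index=r.index, modal_host=r.modal_host,
            )
            for r in records
        ]
    )
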