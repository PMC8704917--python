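"""Core data model for pooled plant-pollinator visitation networks.

A visitation survey yields long-format records (plant, pollinator, site,
date, count).  Pooling across sites and dates produces the bipartite count
matrix ``counts`` with plants as rows and pollinators as columns; the entry
``counts[i, k]`` is the total number of interaction events observed between
plant *i* and pollinator *k*.  Everything downstream (composition distances,
null models, modularity, species roles, indirect-influence indices) operates
on this matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input table does not conform to the expected layout."""


@dataclass(frozen=True)
class VisitationRecord:
    """One observed batch of plant-pollinator interaction events."""

    plant: str
    pollinator: str
    site: str | None = None
    date: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if not self.plant or not self.pollinator:
            raise ValueError("plant and pollinator labels must be non-empty")
        if int(self.count) < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class InteractionNetwork:
    """Plants x pollinators count matrix with labels and functional groups.

    Invariants: no all-zero row or column (a species enters the network only
    through at least one interaction); labels are unique and ordered.
    """

    counts: np.ndarray
    plant_labels: list[str]
    pollinator_labels: list[str]
    plant_groups: dict[str, str] = field(default_factory=dict)
    pollinator_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.plant_labels), len(self.pollinator_labels)):
            raise ValueError("counts shape does not match label lengths")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() < 1:
            raise ValueError("network must contain at least one interaction")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("all-zero plant row in network")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("all-zero pollinator column in network")
        for label in list(self.plant_labels):
            self.plant_groups.setdefault(label, "unknown")
        for label in list(self.pollinator_labels):
            self.pollinator_groups.setdefault(label, "unknown")

    # -- derived margins ---------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.plant_labels)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_labels)

    @property
    def row_totals(self) -> np.ndarray:
        """Interaction events per plant (R_i)."""
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Interaction events per pollinator (C_k)."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        """Grand total of interaction events (F)."""
        return int(self.counts.sum())

    def plant_index(self, label: str) -> int:
        try:
            return self.plant_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown plant {label!r}; valid plants: {', '.join(self.plant_labels)}"
            ) from None


DEFAULT_DIALECT = {
    "plant": "plant",
    "pollinator": "pollinator",
    "site": "site",
    "date": "date",
    "count": "count",
}


def read_visitation_records(
    source, dialect: Mapping[str, str] | None = None
) -> list[VisitationRecord]:
    """Read long-format visitation records from a CSV file or stream.

    Required columns: plant, pollinator.  Optional: site, date, count
    (missing count column means one event per row).  ``dialect`` remaps
    logical column names to the file's actual headers.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    for logical in ("plant", "pollinator"):
        if names[logical] not in df.columns:
            raise FormatError(
                f"missing required column {names[logical]!r} (for {logical})"
            )
    has_count = names["count"] in df.columns
    records: list[VisitationRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        plant = str(row[names["plant"]]).strip()
        pollinator = str(row[names["pollinator"]]).strip()
        if not plant or not pollinator:
            raise FormatError(f"row {idx}: empty plant or pollinator label")
        count = 1
        if has_count:
            raw = str(row[names["count"]]).strip()
            try:
                count = int(raw)
            except ValueError:
                raise FormatError(f"row {idx}: non-integer count {raw!r}") from None
            if count <= 0:
                raise FormatError(f"row {idx}: count must be positive, got {count}")
        records.append(
            VisitationRecord(
                plant=plant,
                pollinator=pollinator,
                site=str(row.get(names["site"], "")) or None,
                date=str(row.get(names["date"], "")) or None,
                count=count,
            )
        )
    return records


def read_annotations(source) -> dict[str, str]:
    """Read a two-column (species, group) CSV into a mapping."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("annotation table needs two columns: species, group")
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def pool_records(
    records: Iterable[VisitationRecord],
    plant_groups: Mapping[str, str] | None = None,
    pollinator_groups: Mapping[str, str] | None = None,
) -> InteractionNetwork:
    """Pool records across sites and dates into an interaction network.

    Labels are sorted lexicographically so that every downstream seeded
    computation is reproducible regardless of record order.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot pool an empty record list")
    plants = sorted({r.plant for r in records})
    pollinators = sorted({r.pollinator for r in records})
    p_index = {p: i for i, p in enumerate(plants)}
    k_index = {k: j for j, k in enumerate(pollinators)}
    counts = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
    for r in records:
        counts[p_index[r.plant], k_index[r.pollinator]] += r.count
    return InteractionNetwork(
        counts=counts,
        plant_labels=plants,
        pollinator_labels=pollinators,
        plant_groups={p: (plant_groups or {}).get(p, "unknown") for p in plants},
        pollinator_groups={
            k: (pollinator_groups or {}).get(k, "unknown") for k in pollinators
        },
    )


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryReport:
    """Visit-share summary of a pooled network (percentages of all events)."""

    total_interactions: int
    n_plants: int
    n_pollinators: int
    plant_shares: pd.DataFrame        # plant, group, visits, share_pct
    pollinator_shares: pd.DataFrame   # pollinator, group, visits, share_pct,
                                      # plants_visited, plants_visited_pct
    plant_group_shares: pd.DataFrame  # group, visits, share_pct, n_species
    pollinator_group_shares: pd.DataFrame


def network_summary(net: InteractionNetwork) -> SummaryReport:
    """Per-species and per-functional-group visit shares, 2-decimal style."""
    F = net.total
    R = net.row_totals
    C = net.col_totals
    plant_df = pd.DataFrame(
        {
            "plant": net.plant_labels,
            "group": [net.plant_groups[p] for p in net.plant_labels],
            "visits": R,
            "share_pct": np.round(100.0 * R / F, 2),
        }
    ).sort_values("visits", ascending=False, kind="stable").reset_index(drop=True)
    plants_visited = (net.counts > 0).sum(axis=0)
    poll_df = pd.DataFrame(
        {
            "pollinator": net.pollinator_labels,
            "group": [net.pollinator_groups[k] for k in net.pollinator_labels],
            "visits": C,
            "share_pct": np.round(100.0 * C / F, 2),
            "plants_visited": plants_visited,
            "plants_visited_pct": np.round(100.0 * plants_visited / net.n_plants, 2),
        }
    ).sort_values("visits", ascending=False, kind="stable").reset_index(drop=True)

    def _group_shares(df: pd.DataFrame, species_col: str) -> pd.DataFrame:
        g = (
            df.groupby("group", as_index=False)
            .agg(visits=("visits", "sum"), n_species=(species_col, "count"))
        )
        g["share_pct"] = np.round(100.0 * g["visits"] / F, 2)
        return g.sort_values("visits", ascending=False, kind="stable").reset_index(
            drop=True
        )

    return SummaryReport(
        total_interactions=F,
        n_plants=net.n_plants,
        n_pollinators=net.n_pollinators,
        plant_shares=plant_df,
        pollinator_shares=poll_df,
        plant_group_shares=_group_shares(plant_df, "plant"),
        pollinator_group_shares=_group_shares(poll_df, "pollinator"),
    )


@dataclass
class SharingReport:
    """How much of a focal plant's pollinator fauna is shared with the rest
    of the network, and how much of its visitation comes from visitors seen
    on no other plant."""

    focal: str
    n_interactions: int
    n_visitor_taxa: int
    shared_taxa_pct: float
    unique_taxa_pct: float
    unique_interaction_pct: float


def shared_pollinator_stats(net: InteractionNetwork, focal: str) -> SharingReport:
    """Shared/unique visitor statistics for a focal plant.

    A visitor of the focal plant is *shared* iff it interacts with at least
    one other plant in the network; the unique-interaction share is the
    fraction of the focal plant's events contributed by its unshared
    visitors.
    """
    i = net.plant_index(focal)
    focal_row = net.counts[i]
    visitors = np.flatnonzero(focal_row)
    others = np.delete(net.counts, i, axis=0)
    if others.shape[0] == 0:
        shared = np.zeros(0, dtype=int)
    else:
        shared = visitors[others[:, visitors].sum(axis=0) > 0]
    n_taxa = len(visitors)
    n_shared = len(shared)
    unique_cols = np.setdiff1d(visitors, shared)
    R_focal = focal_row.sum()
    return SharingReport(
        focal=focal,
        n_interactions=int(R_focal),
        n_visitor_taxa=n_taxa,
        shared_taxa_pct=round(100.0 * n_shared / n_taxa, 2),
        unique_taxa_pct=round(100.0 * (n_taxa - n_shared) / n_taxa, 2),
        unique_interaction_pct=round(100.0 * focal_row[unique_cols].sum() / R_focal, 2),
    )


# ---------------------------------------------------------------------------
# Matrix serialization (TSV, plants as rows, labels in first row/column)
# ---------------------------------------------------------------------------

def write_matrix_tsv(net: InteractionNetwork, path) -> None:
    df = pd.DataFrame(net.counts, index=net.plant_labels, columns=net.pollinator_labels)
    df.to_csv(path, sep="\t", index_label="plant")


def read_matrix_tsv(
    path,
    plant_groups: Mapping[str, str] | None = None,
    pollinator_groups: Mapping[str, str] | None = None,
) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return InteractionNetwork(
        counts=df.to_numpy(dtype=np.int64),
        plant_labels=[str(x) for x in df.index],
        pollinator_labels=[str(x) for x in df.columns],
        plant_groups=dict(plant_groups or {}),
        pollinator_groups=dict(pollinator_groups or {}),
    )


def records_to_csv(records: Sequence[VisitationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "plant": r.plant,
                "pollinator": r.pollinator,
                "site": r.site or "",
                "date": r.date or "",
                "count": r.count,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def records_from_string(text: str) -> list[VisitationRecord]:
    """Convenience: parse records from an in-memory CSV string."""
    return read_visitation_records(io.StringIO(text))
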