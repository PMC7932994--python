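"""Summary arithmetic over clustering and differential-expansion results."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trajectory import ClusterResult


def expander_share(membership_pct: pd.Series | Mapping[int, float],
                   clusters: Sequence[int]) -> float:
    """Percentage of clustered clones allocated to the given clusters
    (sum of their membership percentages)."""
    pct = pd.Series(membership_pct, dtype=float)
    missing = [c for c in clusters if c not in pct.index]
    if missing:
        raise KeyError(f"unknown cluster(s): {missing}")
    return float(pct.loc[list(clusters)].sum())


def impact_share(impacts: pd.Series | Mapping[int, float],
                 clusters: Sequence[int]) -> float:
    """Collective repertoire impact (%) of the given clusters at one timepoint."""
    imp = pd.Series(impacts, dtype=float)
    return float(imp.loc[list(clusters)].sum())


def allocate_labelled_clones(
    assignments: pd.Series, labelled_ids: Iterable[str]
) -> pd.DataFrame:
    """Allocate a labelled clone set (e.g. the DOE list) to clusters.

    Returns one row per cluster with the number of labelled members, plus
    an ``excluded`` row for labelled clones absent from the clustering
    (e.g. filtered out for single-replicate presence).  Counts sum to the
    size of the labelled set.
    """
    ids = list(labelled_ids)
    in_clustering = [i for i in ids if i in assignments.index]
    excluded = len(ids) - len(in_clustering)
    per_cluster = assignments.loc[in_clustering].value_counts().sort_index()
    rows = [dict(cluster=str(c), n=int(n)) for c, n in per_cluster.items()]
    rows.append(dict(cluster="excluded", n=excluded))
    df = pd.DataFrame(rows)
    df.attrs["total"] = int(df["n"].sum())
    return df


def cluster_report(result: ClusterResult, impacts: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Per-cluster membership and repertoire impact across timepoints."""
    out = result.membership().set_index("cluster")
    for name, series in impacts.items():
        out[name] = series
    return out.reset_index()
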