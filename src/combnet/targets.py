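"""Protein-target scoring of drug clusters and hypergeometric enrichment.

Given a drug → protein-target map and a two-cluster drug partition, each
protein P is scored by the (natural) log ratio of distinct targeting drugs
per cluster, S(P) = ln(f1/f2). Proteins with S > ln 2 are preferentially
targeted by cluster 1 (PPT1), those with S < ln 0.5 by cluster 2 (PPT2);
exclusive sets G1/G2 instead require at least ``min_in`` drugs from the
focal cluster and at most ``max_out`` from the other. Enrichment of protein
sets against user-supplied annotation terms uses the upper-tail
hypergeometric test with Benjamini–Hochberg FDR and fold enrichment
(k/n)/(K/N).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .network import ClusterAssignment

__all__ = [
    "DrugTargetMap",
    "ProteinScore",
    "score_proteins",
    "preferential_sets",
    "exclusive_sets",
    "hypergeom_enrichment",
    "overlap_test",
    "read_target_tsv",
    "read_gmt",
]


@dataclass
class DrugTargetMap:
    """Mapping drug id → set of protein-target ids."""

    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        empty = [d for d, p in self.targets.items() if not p]
        if empty:
            raise ValueError(f"drugs with empty target sets: {empty[:5]}")

    def cluster_targets(self, clusters: ClusterAssignment, cid: int) -> set[str]:
        """T_c: union of targets of the drugs assigned to community ``cid``."""
        out: set[str] = set()
        for d, prots in self.targets.items():
            if clusters.labels.get(d) == cid:
                out |= prots
        return out

    def all_targets(self) -> set[str]:
        out: set[str] = set()
        for p in self.targets.values():
            out |= p
        return out


@dataclass
class ProteinScore:
    protein: str
    f1: int  # distinct cluster-1 drugs targeting this protein
    f2: int
    score: float  # ln(f1/f2); ±inf sentinel when one count is zero


def _drug_counts(
    tmap: DrugTargetMap, clusters: ClusterAssignment, pair: tuple[int, int]
) -> dict[str, list[int]]:
    c1, c2 = pair
    counts: dict[str, list[int]] = {}
    unclustered = [d for d in tmap.targets if d not in clusters.labels]
    if unclustered:
        warnings.warn(
            f"{len(unclustered)} drugs in the target map are unclustered and ignored",
            stacklevel=3,
        )
    for d, prots in tmap.targets.items():
        cid = clusters.labels.get(d)
        if cid not in (c1, c2):
            continue
        slot = 0 if cid == c1 else 1
        for p in prots:
            counts.setdefault(p, [0, 0])[slot] += 1
    return counts


def score_proteins(
    tmap: DrugTargetMap,
    clusters: ClusterAssignment,
    pair: tuple[int, int] = (1, 2),
    pseudocount: float = 0.0,
) -> list[ProteinScore]:
    """Score every targeted protein by S = ln(f1/f2) over distinct drugs.

    With ``pseudocount=0`` (default) a zero count yields a ±inf sentinel
    score: f2 = 0 (and f1 ≥ 1) gives +inf, f1 = 0 gives −inf. A positive
    pseudocount is added to both counts instead.
    """
    if not tmap.targets:
        raise ValueError("empty drug-target map")
    counts = _drug_counts(tmap, clusters, pair)
    out = []
    for p in sorted(counts):
        f1, f2 = counts[p]
        if pseudocount > 0:
            s = math.log((f1 + pseudocount) / (f2 + pseudocount))
        elif f1 > 0 and f2 > 0:
            s = math.log(f1 / f2)
        elif f1 > 0:
            s = math.inf
        elif f2 > 0:
            s = -math.inf
        else:  # unreachable: protein only present via a targeting drug
            continue
        out.append(ProteinScore(protein=p, f1=f1, f2=f2, score=s))
    return out


def preferential_sets(
    scores: list[ProteinScore], threshold: float = math.log(2.0), strict: bool = True
) -> tuple[set[str], set[str]]:
    """Split proteins into PPT1 (S > ln 2) and PPT2 (S < ln 0.5).

    Thresholds are strict inequalities by default: a protein at exactly
    S = ln 2 (e.g. f1=4, f2=2) belongs to neither set.
    """
    if strict:
        ppt1 = {s.protein for s in scores if s.score > threshold}
        ppt2 = {s.protein for s in scores if s.score < -threshold}
    else:
        ppt1 = {s.protein for s in scores if s.score >= threshold}
        ppt2 = {s.protein for s in scores if s.score <= -threshold}
    return ppt1, ppt2


def exclusive_sets(
    tmap: DrugTargetMap,
    clusters: ClusterAssignment,
    min_in: int = 3,
    max_out: int = 2,
    pair: tuple[int, int] = (1, 2),
) -> tuple[set[str], set[str]]:
    """G1 = proteins hit by ≥ min_in cluster-1 drugs and ≤ max_out cluster-2
    drugs; G2 symmetric. Overlap is possible only when min_in ≤ max_out."""
    if min_in <= 0:
        raise ValueError("min_in must be positive")
    counts = _drug_counts(tmap, clusters, pair)
    g1 = {p for p, (f1, f2) in counts.items() if f1 >= min_in and f2 <= max_out}
    g2 = {p for p, (f1, f2) in counts.items() if f2 >= min_in and f1 <= max_out}
    if g1 & g2 and min_in <= max_out:
        warnings.warn("G1 and G2 overlap (min_in <= max_out)", stacklevel=2)
    return g1, g2


def hypergeom_enrichment(
    query: set[str],
    annotations: dict[str, set[str]],
    background: set[str],
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a protein set in annotation terms.

    For each term with K background members, the p-value is P(X ≥ k) for a
    hypergeometric draw of n = |query| from N = |background|; fold enrichment
    is (k/n)/(K/N). P-values are BH-adjusted; rows are sorted by p.
    """
    if not background:
        raise ValueError("empty background")
    stray = query - background
    if stray:
        raise ValueError(f"query proteins outside background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(query)
    rows = []
    for term, members in annotations.items():
        mem = members & background
        K = len(mem)
        if K == 0:
            continue
        k = len(query & mem)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append((term, k, n, K, N, fold, p))
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "fold_enrichment", "p_value"]
    )
    if len(df):
        df["fdr"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
        df["significant"] = df["fdr"] < fdr_alpha
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


def overlap_test(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric probability of ≥ |A∩B| shared elements."""
    if not universe:
        raise ValueError("empty universe")
    if set_a - universe or set_b - universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))


def read_target_tsv(path) -> DrugTargetMap:
    """Read a two-column drug<TAB>protein file into a DrugTargetMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["drug", "protein"], dtype=str)
    targets: dict[str, set[str]] = {}
    for drug, prot in zip(df["drug"], df["protein"]):
        targets.setdefault(drug, set()).add(prot)
    return DrugTargetMap(targets=targets)


def write_target_tsv(tmap: DrugTargetMap, path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(tmap.targets):
            for prot in sorted(tmap.targets[drug]):
                fh.write(f"{drug}\t{prot}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT-format annotation sets: term<TAB>description<TAB>members..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out
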