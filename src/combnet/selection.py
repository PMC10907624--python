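"""Efficacy/toxicity drug profiling, candidate selection, proportion tests.

For each drug, efficacy is its mean normalized inhibition over patient
samples and toxicity the mean over healthy-donor samples. Candidate drugs
for combination testing must beat both grand means (toxicity below average,
efficacy above average); the top 5% by efficacy − toxicity are kept, capped
per cluster. Pairing the selected drugs yields inter-cluster (positive) and
intra-cluster (negative) combinations; with four drugs per cluster that is
16 inter and 12 intra pairs.

The evaluation statistic is a proportion test: is the fraction of
inter-cluster combinations that land in the "good" corner — efficacy above
the third quartile of all combination efficacies AND toxicity below the
first quartile of all toxicities — higher than a null probability of 0.33?
The same machinery runs on synergy scores and combination ratios (high on
patients, low on healthy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import ClusterAssignment
from .response import ResponseMatrix

__all__ = [
    "DrugProfile",
    "ProportionTestResult",
    "profile_drugs",
    "select_candidates",
    "label_combinations",
    "proportion_test",
]


@dataclass
class DrugProfile:
    drug_id: str
    efficacy: float  # mean inhibition over patient samples
    toxicity: float  # mean inhibition over healthy samples
    cluster: int | None = None


@dataclass
class ProportionTestResult:
    successes: int
    trials: int
    p0: float
    p_value: float
    q3_threshold: float  # efficacy must exceed this (Q3 over all combinations)
    q1_threshold: float  # toxicity must stay below this (Q1 over all)
    mode: str = "exact_binomial"


def profile_drugs(
    m: ResponseMatrix, clusters: ClusterAssignment | None = None
) -> list[DrugProfile]:
    """Per-drug efficacy/toxicity as means over patient/healthy samples."""
    pat = m.patient_index
    hea = m.healthy_index
    if not pat.any():
        raise ValueError("response matrix has no patient samples")
    if not hea.any():
        raise ValueError("response matrix has no healthy samples")
    eff = m.a[pat].mean(axis=0)
    tox = m.a[hea].mean(axis=0)
    out = []
    for j, d in enumerate(m.drug_ids):
        cid = clusters.labels.get(d) if clusters is not None else None
        out.append(
            DrugProfile(drug_id=d, efficacy=float(eff[j]), toxicity=float(tox[j]), cluster=cid)
        )
    return out


def select_candidates(
    profiles: list[DrugProfile],
    fraction: float = 0.05,
    per_cluster: int = 4,
    rank_by: str = "margin",
) -> list[DrugProfile]:
    """Select candidate drugs: better-than-average on both axes, then top 5%.

    Filters to drugs with toxicity strictly below the mean toxicity and
    efficacy strictly above the mean efficacy of *all* drugs, ranks the
    survivors (``margin`` = efficacy − toxicity descending, ``efficacy`` =
    efficacy descending; ties broken by drug id), keeps the top
    ⌈fraction × n_drugs⌉ overall and then at most ``per_cluster`` per
    cluster. May return an empty list (with no drug beating both means).
    """
    if not profiles:
        return []
    mean_eff = float(np.mean([p.efficacy for p in profiles]))
    mean_tox = float(np.mean([p.toxicity for p in profiles]))
    passing = [
        p for p in profiles if p.efficacy > mean_eff and p.toxicity < mean_tox
    ]
    if rank_by == "margin":
        key = lambda p: (-(p.efficacy - p.toxicity), p.drug_id)
    elif rank_by == "efficacy":
        key = lambda p: (-p.efficacy, p.drug_id)
    else:
        raise ValueError("rank_by must be 'margin' or 'efficacy'")
    passing.sort(key=key)
    cap = math.ceil(fraction * len(profiles))
    passing = passing[:cap]
    taken: dict[int | None, int] = {}
    out = []
    for p in passing:
        if taken.get(p.cluster, 0) < per_cluster:
            out.append(p)
            taken[p.cluster] = taken.get(p.cluster, 0) + 1
    return out


def label_combinations(
    pairs: list[tuple[str, str]], clusters: ClusterAssignment
) -> pd.DataFrame:
    """Label drug pairs as inter-cluster or intra-cluster (intra_<cid>)."""
    rows = []
    for d1, d2 in pairs:
        if d1 == d2:
            raise ValueError(f"self-combination {d1!r} is not allowed")
        for d in (d1, d2):
            if d not in clusters.labels:
                raise ValueError(f"drug {d!r} has no cluster assignment")
        c1, c2 = clusters.labels[d1], clusters.labels[d2]
        group = "inter" if c1 != c2 else f"intra_{c1}"
        rows.append((d1, d2, group))
    return pd.DataFrame(rows, columns=["drug1", "drug2", "group"])


def all_pairs(drugs: list[str]) -> list[tuple[str, str]]:
    """Every unordered pair of distinct drugs, in id order."""
    ds = sorted(drugs)
    return [(ds[i], ds[j]) for i in range(len(ds)) for j in range(i + 1, len(ds))]


def proportion_test(
    records: pd.DataFrame,
    metric_pair: tuple[str, str] = ("efficacy", "toxicity"),
    p0: float = 0.33,
    mode: str = "exact_binomial",
) -> ProportionTestResult:
    """One-sided proportion test that inter-cluster combinations enrich the
    high-benefit corner beyond chance.

    A combination succeeds when its first metric exceeds the third quartile
    of that metric over ALL combinations and its second metric falls below
    the first quartile of the second metric over all combinations (linear-
    interpolation quantiles). The test asks whether the success proportion
    among inter-cluster records exceeds ``p0``; the default is the exact
    binomial tail, with a normal approximation available.
    """
    hi_col, lo_col = metric_pair
    if "group" not in records.columns:
        raise ValueError("records need a 'group' column")
    inter = records[records["group"] == "inter"]
    n = len(inter)
    if n == 0:
        raise ValueError("no inter-cluster combinations to test")
    q3 = float(np.quantile(records[hi_col].to_numpy(), 0.75))
    q1 = float(np.quantile(records[lo_col].to_numpy(), 0.25))
    k = int(((inter[hi_col] > q3) & (inter[lo_col] < q1)).sum())
    if mode == "exact_binomial":
        p = float(stats.binomtest(k, n, p0, alternative="greater").pvalue)
    elif mode == "normal_approx":
        se = math.sqrt(p0 * (1 - p0) / n)
        z = (k / n - p0) / se
        p = float(stats.norm.sf(z))
    else:
        raise ValueError("mode must be 'exact_binomial' or 'normal_approx'")
    return ProportionTestResult(
        successes=k,
        trials=n,
        p0=p0,
        p_value=p,
        q3_threshold=q3,
        q1_threshold=q1,
        mode=mode,
    )
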