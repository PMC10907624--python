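"""Chemical-structure similarity of drug clusters via fingerprint Dice indices.

Each drug is a binary fingerprint (ECFP bits or synthetic); the Dice
similarity of molecules A and B is S = 2c/(a+b) where a and b count the ON
bits of each molecule and c the shared ON bits. Cluster homogeneity is the
claim that drugs within a response-based cluster are also structurally more
alike than drugs across clusters: intra-cluster pairwise Dice values should
stochastically exceed inter-cluster ones.

:func:`homogeneity_test` reports one-sided Welch t and Mann–Whitney p-values
for "inter < intra" (per cluster and pooled). Pairwise similarities sharing
a drug are not independent, which both tests ignore; a label-permutation
p-value on the difference of group means is computed alongside as the
calibrated variant and is the one to trust for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import ClusterAssignment

__all__ = [
    "Fingerprint",
    "HomogeneityResult",
    "dice",
    "dice_matrix",
    "homogeneity_test",
    "read_fingerprint_tsv",
    "smiles_to_fingerprint",
]


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary fingerprint: the set of ON bit positions."""

    drug_id: str
    on_bits: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        if self.on_bits and (min(self.on_bits) < 0 or max(self.on_bits) >= self.n_bits):
            raise ValueError("on_bits outside [0, n_bits)")


def dice(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Dice similarity 2c/(a+b) of two fingerprints; symmetric, in [0, 1]."""
    a = len(fp_a.on_bits)
    b = len(fp_b.on_bits)
    if a + b == 0:
        raise ValueError("Dice similarity undefined for two empty fingerprints")
    c = len(fp_a.on_bits & fp_b.on_bits)
    return 2.0 * c / (a + b)


def dice_matrix(fps: list[Fingerprint]) -> np.ndarray:
    """All-pairs Dice similarity matrix, computed via dense bit matrices."""
    n = len(fps)
    n_bits = max(fp.n_bits for fp in fps)
    m = np.zeros((n, n_bits), dtype=np.float64)
    for i, fp in enumerate(fps):
        if fp.on_bits:
            m[i, list(fp.on_bits)] = 1.0
    counts = m.sum(axis=1)
    shared = m @ m.T
    denom = counts[:, None] + counts[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 2.0 * shared / denom
    d[denom == 0] = np.nan
    return d


@dataclass
class HomogeneityResult:
    """Intra- vs inter-cluster Dice samples and one-sided test p-values."""

    intra: dict[int, np.ndarray]  # cluster id -> pairwise Dice values
    inter: np.ndarray
    means: dict[str, float]
    p_t: dict[str, float]  # Welch t, H1: mean(inter) < mean(intra)
    p_wilcoxon: dict[str, float]  # Mann-Whitney U, same direction
    p_permutation: dict[str, float] | None = None
    degenerate: bool = False


def _one_sided_less(inter: np.ndarray, intra: np.ndarray) -> tuple[float, float]:
    """p-values for H1: inter-cluster similarities < intra-cluster ones."""
    if np.std(inter) == 0 and np.std(intra) == 0:
        return 1.0, 1.0
    t = stats.ttest_ind(inter, intra, equal_var=False, alternative="less")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = stats.mannwhitneyu(inter, intra, alternative="less")
    return float(t.pvalue), float(u.pvalue)


def homogeneity_test(
    fps: list[Fingerprint],
    clusters: ClusterAssignment,
    n_permutations: int = 0,
    seed: int = 0,
) -> HomogeneityResult:
    """Test whether intra-cluster Dice similarities exceed inter-cluster ones.

    Computes every pairwise Dice value within each cluster and across the two
    largest clusters, then one-sided Welch t and Mann–Whitney tests of
    "inter < intra" against each intra group and against the pooled intra
    values. With ``n_permutations > 0``, a permutation p-value for the
    difference of means (pooled intra − inter) under random relabeling of
    drugs is added; it is exact under exchangeability and is the variant that
    remains calibrated despite the dependence between pairs sharing a drug.
    """
    fps = [fp for fp in fps if fp.drug_id in clusters.labels]
    labels = np.array([clusters.labels[fp.drug_id] for fp in fps])
    cids = sorted(
        set(labels.tolist()),
        key=lambda c: (-int((labels == c).sum()), c),
    )[:2]
    if len(cids) < 2:
        raise ValueError("need at least two clusters with fingerprints")
    keep = np.isin(labels, cids)
    fps = [fp for fp, k in zip(fps, keep) if k]
    labels = labels[keep]
    d = dice_matrix(fps)
    iu = np.triu_indices(len(fps), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = d[iu]

    intra: dict[int, np.ndarray] = {}
    degenerate = False
    for c in cids:
        both = (labels[iu[0]] == c) & (labels[iu[1]] == c)
        if both.sum() < 1:
            warnings.warn(f"cluster {c} has < 2 fingerprints; intra group omitted")
            continue
        intra[c] = vals[both]
    inter = vals[~same]

    pooled = np.concatenate(list(intra.values())) if intra else np.array([])
    means = {f"intra_{c}": float(v.mean()) for c, v in intra.items()}
    means["inter"] = float(inter.mean()) if inter.size else np.nan
    p_t: dict[str, float] = {}
    p_w: dict[str, float] = {}
    for c, v in intra.items():
        p_t[f"intra_{c}"], p_w[f"intra_{c}"] = _one_sided_less(inter, v)
    if pooled.size:
        p_t["pooled"], p_w["pooled"] = _one_sided_less(inter, pooled)
        if np.std(pooled) == 0 and np.std(inter) == 0:
            degenerate = True

    p_perm = None
    if n_permutations > 0 and pooled.size:
        rng = np.random.default_rng(seed)
        obs = float(pooled.mean() - inter.mean())
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            psame = perm[iu[0]] == perm[iu[1]]
            stat = float(vals[psame].mean() - vals[~psame].mean())
            if stat >= obs:
                count += 1
        p_perm = {"pooled": (count + 1) / (n_permutations + 1)}

    return HomogeneityResult(
        intra=intra,
        inter=inter,
        means=means,
        p_t=p_t,
        p_wilcoxon=p_w,
        p_permutation=p_perm,
        degenerate=degenerate,
    )


def read_fingerprint_tsv(path, n_bits: int | None = None) -> list[Fingerprint]:
    """Read fingerprints: drug<TAB>bitstring ('0101...') or comma-separated
    ON-bit indices. ``n_bits`` is required for the index form."""
    fps = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            drug, payload = line.split("\t", 1)
            if set(payload) <= {"0", "1"}:
                bits = frozenset(i for i, ch in enumerate(payload) if ch == "1")
                length = len(payload)
            else:
                bits = frozenset(int(x) for x in payload.split(",") if x)
                if n_bits is None:
                    raise ValueError("n_bits required for index-form fingerprints")
                length = n_bits
            fps.append(Fingerprint(drug_id=drug, on_bits=bits, n_bits=length))
    return fps


def write_fingerprint_tsv(fps: list[Fingerprint], path) -> None:
    with open(path, "w") as fh:
        for fp in fps:
            bits = ["0"] * fp.n_bits
            for b in fp.on_bits:
                bits[b] = "1"
            fh.write(f"{fp.drug_id}\t{''.join(bits)}\n")


def smiles_to_fingerprint(
    drug_id: str, smiles: str, n_bits: int = 2048, radius: int = 2
) -> Fingerprint:
    """Morgan/ECFP fingerprint from a SMILES string (requires rdkit)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES for {drug_id}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(
        drug_id=drug_id, on_bits=frozenset(fp.GetOnBits()), n_bits=n_bits
    )
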