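"""Out-of-distribution train/test split construction and similarity pruning.

A test set probes generalisation only if no test complex resembles the
training data in ligand chemistry, protein sequence, or binding pocket.
The split here works on a combined complex distance

    d(c1, c2) = 1 - max(s(c1, c2)/100, T_s(c1, c2)),

where T_s is the Tanimoto similarity of ligand ECFP6 (Morgan radius-3)
fingerprints and s the percent sequence identity (the maximum over all
chain pairs for multi-chain complexes).  Complexes are grouped by
agglomerative single-linkage clustering with a distance threshold of 0.5 --
equivalently, connected components of the graph joining pairs with
d < 0.5 -- so train and test clusters share neither a similar ligand
(T_s >= 0.5) nor a similar sequence (identity >= 50%).

Test clusters must also look drug-like (no ligand above 1000 Da, none with
more than 20 rotatable bonds) and, when pocket family labels are supplied,
must not share a pocket label with any training complex.  A separate
pruning utility removes training complexes whose ligands exceed a Tanimoto
ceiling against any test ligand, used to study performance as a function
of train/test similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from Bio import Align

from .complex_io import LigandMolecule, ProteinStructure, ligand_to_rdkit

ECFP6_RADIUS = 3
ECFP6_BITS = 2048


# ---------------------------------------------------------------------------
# similarities
# ---------------------------------------------------------------------------

def ecfp6_fingerprint(ligand, n_bits: int = ECFP6_BITS):
    """ECFP6 (Morgan radius-3) bit fingerprint of a ligand.

    Accepts a :class:`LigandMolecule` or an RDKit Mol.
    """
    mol = ligand_to_rdkit(ligand) if isinstance(ligand, LigandMolecule) else ligand
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=ECFP6_RADIUS, fpSize=n_bits
    )
    fp = gen.GetFingerprint(mol)
    if fp.GetNumOnBits() == 0:
        raise ValueError("empty fingerprint")
    return fp


def tanimoto_similarity(lig1, lig2) -> float:
    """Tanimoto similarity |A&B| / |A|B| of ECFP6 fingerprints, in [0, 1]."""
    return float(
        DataStructs.TanimotoSimilarity(
            ecfp6_fingerprint(lig1), ecfp6_fingerprint(lig2)
        )
    )


def _pairwise_identity(seq1: str, seq2: str) -> float:
    """Percent identity from a global alignment: matches / alignment length."""
    if not seq1 or not seq2:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq1, seq2)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for ca, cb in zip(a, b) if ca == cb and ca != "-")
    return 100.0 * matches / len(a)


def sequence_identity(
    p1: ProteinStructure,
    p2: ProteinStructure,
    provider: Optional[Callable[[str, str], float]] = None,
) -> float:
    """Percent sequence identity in [0, 100]; max over all chain pairs.

    ``provider(seq1, seq2) -> percent`` is pluggable (e.g. an external
    aligner); the default is a built-in global pairwise alignment.
    """
    if not p1.chains or not p2.chains:
        raise ValueError("both proteins need at least one chain")
    provider = provider or _pairwise_identity
    return max(provider(a, b) for a in p1.chains for b in p2.chains)


def complex_distance(ts: float, seq_id: float) -> float:
    """d = 1 - max(s/100, T_s); zero iff either similarity is maximal."""
    return 1.0 - max(seq_id / 100.0, ts)


def distance_matrix(ts_matrix: np.ndarray, seq_matrix: np.ndarray) -> np.ndarray:
    """Combined complex distance matrix from Tanimoto and identity matrices."""
    ts = np.asarray(ts_matrix, dtype=float)
    s = np.asarray(seq_matrix, dtype=float)
    if ts.shape != s.shape or ts.shape[0] != ts.shape[1]:
        raise ValueError("similarity matrices must be square and congruent")
    d = 1.0 - np.maximum(s / 100.0, ts)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# clustering and split assembly
# ---------------------------------------------------------------------------

def single_linkage_cluster(
    distances: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Single-linkage cluster labels; pairs merge iff chained by d < threshold.

    Equivalent to connected components of the graph with edges d < threshold.
    Returns integer labels (0-based, ordered by first occurrence).
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square symmetric")
    n = d.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method="single")
    # fcluster cuts at <= t; the split semantics are strict <
    labels = fcluster(Z, t=np.nextafter(threshold, -np.inf), criterion="distance")
    # relabel by first occurrence for determinism
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        out[i] = remap.setdefault(int(lab), len(remap))
    return out


@dataclass
class SplitResult:
    test_ids: list[str]
    train_ids: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        test, train = set(self.test_ids), set(self.train_ids)
        excl = {cid for cid, _ in self.excluded}
        if test & train or test & excl or train & excl:
            raise ValueError("split lists overlap")


def assemble_ood_split(
    ids: Sequence[str],
    cluster_labels: Sequence[int],
    ts_matrix: np.ndarray,
    seq_matrix: np.ndarray,
    ligand_props: Mapping[str, tuple[float, int]],
    pocket_labels: Optional[Mapping[str, object]] = None,
    test_clusters: Optional[Sequence[int]] = None,
    n_test_clusters: Optional[int] = None,
    seed: Optional[int] = None,
    ts_threshold: float = 0.5,
    identity_threshold: float = 50.0,
) -> SplitResult:
    """Assemble an OOD split from clusters, with drug-likeness and pocket filters.

    Candidate test clusters are either given explicitly (``test_clusters``)
    or sampled (``n_test_clusters`` with ``seed``).  A candidate cluster is
    excluded from the test set when it contains a ligand heavier than
    1000 Da (reason "MW") or with more than 20 rotatable bonds (reason
    "rotatable"), or when any of its complexes shares a pocket label with
    the training pool (reason "pocket").  Remaining complexes join the
    training pool only if, against every test complex, T_s < 0.5, sequence
    identity < 50% and the pocket label differs; otherwise they are
    excluded with reason "similarity".
    """
    ids = list(ids)
    n = len(ids)
    labels = np.asarray(cluster_labels, dtype=int)
    ts = np.asarray(ts_matrix, dtype=float)
    s = np.asarray(seq_matrix, dtype=float)
    if labels.size != n or ts.shape != (n, n) or s.shape != (n, n):
        raise ValueError("ids, labels and similarity matrices must agree")
    if pocket_labels is None:
        warnings.warn(
            "no pocket labels supplied; the pocket-overlap filter is SKIPPED"
        )

    clusters = sorted(set(labels.tolist()))
    if test_clusters is None:
        if n_test_clusters is None:
            raise ValueError("give test_clusters or n_test_clusters")
        rng = np.random.default_rng(seed)
        test_clusters = rng.choice(
            clusters, size=min(n_test_clusters, len(clusters)), replace=False
        ).tolist()
    test_clusters = set(int(c) for c in test_clusters)

    excluded: list[tuple[str, str]] = []
    test_idx: list[int] = []
    # drug-likeness filters operate on whole clusters
    for c in sorted(test_clusters):
        members = np.nonzero(labels == c)[0]
        mws = [ligand_props[ids[i]][0] for i in members]
        rots = [ligand_props[ids[i]][1] for i in members]
        if any(mw > 1000.0 for mw in mws):
            excluded.extend((ids[i], "MW") for i in members)
        elif any(r > 20 for r in rots):
            excluded.extend((ids[i], "rotatable") for i in members)
        else:
            test_idx.extend(members.tolist())

    train_pool = [
        i for i in range(n)
        if labels[i] not in test_clusters
    ]
    # pocket-overlap: drop whole test clusters sharing a label with training
    if pocket_labels is not None and test_idx:
        train_labels = {
            pocket_labels.get(ids[i]) for i in train_pool
        } - {None}
        dropped_clusters = {
            int(labels[i]) for i in test_idx
            if pocket_labels.get(ids[i]) in train_labels
        }
        if dropped_clusters:
            kept = []
            for i in test_idx:
                if int(labels[i]) in dropped_clusters:
                    excluded.append((ids[i], "pocket"))
                else:
                    kept.append(i)
            test_idx = kept

    # training pool must be dissimilar to every test complex
    train_idx: list[int] = []
    for i in train_pool:
        ok = True
        for j in test_idx:
            if ts[i, j] >= ts_threshold or s[i, j] >= identity_threshold:
                ok = False
                break
            if pocket_labels is not None:
                li, lj = pocket_labels.get(ids[i]), pocket_labels.get(ids[j])
                if li is not None and li == lj:
                    ok = False
                    break
        if ok:
            train_idx.append(i)
        else:
            excluded.append((ids[i], "similarity"))

    return SplitResult(
        test_ids=[ids[i] for i in test_idx],
        train_ids=[ids[i] for i in train_idx],
        excluded=excluded,
        provenance={
            "ts_threshold": ts_threshold,
            "identity_threshold": identity_threshold,
            "test_clusters": sorted(test_clusters),
            "cluster_labels": {ids[i]: int(labels[i]) for i in range(n)},
            "pocket_filter_applied": pocket_labels is not None,
        },
    )


def prune_training_by_similarity(
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    tanimoto: Callable[[str, str], float],
    ts_max: float,
) -> tuple[list[str], list[tuple[str, float]]]:
    """Drop training complexes whose max T_s to any test ligand exceeds ts_max.

    "Exceeds" is strict: a complex is kept iff max_j T_s <= ts_max, so
    output sets are nested across decreasing thresholds.  Returns
    (kept_ids, removal log of (id, max_ts)).
    """
    kept, removed = [], []
    for tid in train_ids:
        max_ts = max((tanimoto(tid, q) for q in test_ids), default=0.0)
        if max_ts > ts_max:
            removed.append((tid, max_ts))
        else:
            kept.append(tid)
    return kept, removed
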