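"""Synthetic trees, alignments, and cohorts with planted ground truth.

Everything the pipeline consumes can be generated here with known structure:
ultrametric time trees, protein alignments evolved under a Poisson-uniform
substitution process with per-column target rates, and mixed
clinical/molecular cohorts where a small informative subset hides among noise
features and informativeness is (optionally) coupled to high conservation.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import AMINO_ACIDS, Node, ProteinAlignment, TimeTree
from .weighting import FeatureMeta, LabeledMatrix

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "simulate_timetree",
    "simulate_alignment",
    "simulate_cohort",
    "simulate_dataset",
]

_AA = sorted(AMINO_ACIDS)

# conserved genes draw R in [0.5, 1.5] subst/Byr; background in [5, 25]
_LOW_R = (0.5, 1.5)
_BACKGROUND_R = (5.0, 25.0)
_N_CLINICAL = 5


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a planted-structure cohort."""

    m: int = 200
    p: int = 100
    n_informative: int = 5
    effect_size: float = 1.0          # class mean shift in sd units
    class_balance: float = 0.3        # fraction of positive samples
    conservation_coupling: float = 0.9
    noise_correlation: int = 0        # noise features forced to nominal p<.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.p - _N_CLINICAL:
            raise ValueError("n_informative exceeds molecular feature count")
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass
class SyntheticTruth:
    informative_features: list
    assigned_R: dict
    site_rate_profiles: dict = field(default_factory=dict)


def _leaf_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    return [letters[i] if i < 26 else f"T{i}" for i in range(n)]


def simulate_timetree(n_taxa: int, depth_myr: float, seed: int = 0) -> TimeTree:
    """Random ultrametric tree: coalescent merge order, depth rescaled.

    Every leaf sits exactly ``depth_myr`` Myr below the root.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if depth_myr <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)

    # Kingman-style: merge random pairs at increasing heights.
    lineages: list[tuple[Node, float]] = [
        (Node(name), 0.0) for name in _leaf_names(n_taxa)]
    height = 0.0
    k = n_taxa
    while k > 1:
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha) = lineages.pop(j)
        (b, hb) = lineages.pop(i)
        parent = Node()
        a.branch_length = height - ha
        b.branch_length = height - hb
        parent.add_child(b)
        parent.add_child(a)
        lineages.append((parent, height))
        k -= 1

    root, total_height = lineages[0]
    scale = depth_myr / total_height

    def _rescale(node: Node) -> None:
        if node.branch_length is not None:
            node.branch_length *= scale
        for ch in node.children:
            _rescale(ch)

    _rescale(root)
    root.branch_length = None
    return TimeTree(root)


def simulate_alignment(tree: TimeTree, site_rate_profile, gap_prob: float = 0.0,
                       seed: int = 0,
                       reference_taxon: str | None = None) -> ProteinAlignment:
    """Evolve a protein alignment down ``tree`` with per-column target rates.

    The root sequence is uniform over the 20 amino acids; each branch applies
    ``Poisson(rate * branch_Myr / 1000)`` substitution events per column, each
    replacing the state with one of the other 19 uniformly.  Gaps are inserted
    independently per taxon and column with probability ``gap_prob``.
    """
    rates = np.asarray(site_rate_profile, dtype=float)
    if (rates < 0).any():
        raise ValueError("site rates must be >= 0")
    if not (0 <= gap_prob < 1):
        raise ValueError("gap_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_sites = len(rates)

    root_seq = rng.integers(0, 20, size=n_sites)
    leaf_seqs: dict[str, np.ndarray] = {}

    def _evolve(node: Node, seq: np.ndarray) -> None:
        if node.branch_length:
            seq = seq.copy()
            n_events = rng.poisson(rates * node.branch_length / 1000.0)
            for j in np.flatnonzero(n_events):
                for _ in range(n_events[j]):
                    new = rng.integers(0, 19)
                    if new >= seq[j]:
                        new += 1
                    seq[j] = new
        if node.is_leaf:
            leaf_seqs[node.name] = seq
        for ch in node.children:
            _evolve(ch, seq)

    _evolve(tree.root, root_seq)

    names = tree.leaf_names
    rows = []
    for name in names:
        chars = [_AA[c] for c in leaf_seqs[name]]
        if gap_prob > 0:
            mask = rng.random(n_sites) < gap_prob
            chars = ["-" if g else c for c, g in zip(chars, mask)]
        rows.append("".join(chars))
    ref = reference_taxon if reference_taxon is not None else names[0]
    return ProteinAlignment(names, rows, reference_taxon=ref)


def simulate_cohort(spec: SyntheticCohortSpec):
    """Planted-structure cohort: labels, features, metadata, conservation, truth.

    Returns ``(LabeledMatrix, meta DataFrame, conservation DataFrame,
    SyntheticTruth)``.  The first ``_N_CLINICAL`` features are a clinical
    block with moderate effects; informative molecular features shift class
    means by ``effect_size`` sd and are assigned a low evolutionary rate
    (high conservation) with probability ``conservation_coupling``.
    """
    rng = np.random.default_rng(spec.seed)
    m, p = spec.m, spec.p

    n_pos = int(round(spec.class_balance * m))
    n_pos = min(max(n_pos, 2), m - 2)
    y = np.zeros(m, dtype=int)
    pos_idx = rng.choice(m, size=n_pos, replace=False)
    y[pos_idx] = 1

    sample_ids = [f"S{i:04d}" for i in range(m)]
    clinical_ids = [f"clin{i}" for i in range(_N_CLINICAL)]
    n_mol = p - _N_CLINICAL
    mol_ids = [f"mol{i:04d}" for i in range(n_mol)]
    feature_ids = clinical_ids + mol_ids

    informative = list(rng.choice(mol_ids, size=spec.n_informative,
                                  replace=False))
    info_set = set(informative)

    X = rng.normal(size=(m, p))
    cols = {f: j for j, f in enumerate(feature_ids)}
    shift = spec.effect_size
    for f in informative:
        X[y == 1, cols[f]] += shift / 2.0
        X[y == 0, cols[f]] -= shift / 2.0
    for f in clinical_ids:  # moderate clinical effects (half strength)
        X[y == 1, cols[f]] += shift / 4.0
        X[y == 0, cols[f]] -= shift / 4.0

    # spurious-association noise: redraw until nominal p < .05 vs the labels
    if spec.noise_correlation > 0:
        from scipy import stats as _st
        eligible = [f for f in mol_ids if f not in info_set]
        forced = rng.choice(eligible, size=spec.noise_correlation, replace=False)
        for f in forced:
            for _ in range(200):
                col = rng.normal(size=m)
                _, pval = _st.ttest_ind(col[y == 1], col[y == 0])
                if pval < 0.05:
                    X[:, cols[f]] = col
                    break

    # conservation: one gene per molecular feature
    gene_ids = {f: f"g_{f}" for f in mol_ids}
    R = {}
    for f in mol_ids:
        conserved = (f in info_set) and (rng.random() < spec.conservation_coupling)
        lo, hi = _LOW_R if conserved else _BACKGROUND_R
        R[gene_ids[f]] = rng.uniform(lo, hi)
    conservation = pd.DataFrame(
        {"R": pd.Series(R)}).rename_axis("gene_id")
    conservation["WE"] = 1.0 / conservation["R"]

    meta = pd.DataFrame(
        [{"feature_id": f, "kind": "clinical", "gene_id": None}
         for f in clinical_ids]
        + [{"feature_id": f, "kind": "molecular", "gene_id": gene_ids[f]}
           for f in mol_ids])

    matrix = LabeledMatrix(
        X=pd.DataFrame(X, index=sample_ids, columns=feature_ids),
        y=pd.Series(y, index=sample_ids, name="outcome"))
    truth = SyntheticTruth(informative_features=informative,
                           assigned_R={gene_ids[f]: R[gene_ids[f]]
                                       for f in mol_ids})
    return matrix, meta, conservation, truth


def simulate_dataset(spec: SyntheticCohortSpec, out_dir: str, *,
                     n_taxa: int = 12, depth_myr: float = 500.0,
                     n_columns: int = 150, gap_prob: float = 0.05) -> dict:
    """Write a complete file-based fixture set under ``out_dir``.

    Produces ``tree.nwk``, one aligned FASTA per gene (columns evolved at the
    gene's assigned rate), ``features.tsv``, ``meta.tsv``, and ``truth.json``.
    Returns a manifest of the written paths.
    """
    import json
    import os

    matrix, meta, conservation, truth = simulate_cohort(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    tree = simulate_timetree(n_taxa, depth_myr, seed=spec.seed + 1)

    os.makedirs(out_dir, exist_ok=True)
    aln_dir = os.path.join(out_dir, "alignments")
    os.makedirs(aln_dir, exist_ok=True)

    tree_path = os.path.join(out_dir, "tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(tree.newick() + "\n")

    profiles = {}
    for gene_id, row in conservation.iterrows():
        target = float(row["R"])
        rates = rng.gamma(4.0, target / 4.0, size=n_columns)
        profiles[gene_id] = rates.tolist()
        aln = simulate_alignment(tree, rates, gap_prob=gap_prob,
                                 seed=int(rng.integers(2**31)))
        with open(os.path.join(aln_dir, f"{gene_id}.fasta"), "w") as fh:
            fh.write(aln.to_fasta())
    truth.site_rate_profiles = profiles

    features_path = os.path.join(out_dir, "features.tsv")
    table = matrix.X.copy()
    table.insert(0, "outcome", matrix.y)
    table.rename_axis("sample_id").to_csv(features_path, sep="\t")

    meta_path = os.path.join(out_dir, "meta.tsv")
    meta.to_csv(meta_path, sep="\t", index=False)

    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump({"informative_features": truth.informative_features,
                   "assigned_R": truth.assigned_R,
                   "site_rate_profiles": truth.site_rate_profiles}, fh)

    return {"tree": tree_path, "alignments": aln_dir,
            "features": features_path, "meta": meta_path, "truth": truth_path,
            "reference_taxon": tree.leaf_names[0]}
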