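"""Synthetic desk-scale DTI datasets with planted ground truth.

A latent bilinear model drives the generator: every drug i and protein j
get latent vectors u_i, v_j ~ N(0, I); the pair affinity is the normalized
inner product s_ij. The top ``positive_rate`` fraction of pairs by s_ij
are observed POSITIVE; a further high-affinity tranche stays UNKNOWN
(latent positives), and a random subset of the remaining unknowns is
planted as TRUE_NEGATIVE and displaced by ``negative_cluster_shift`` latent
standard deviations away from the positive feature manifold.

Observed pair features embed the latent signal into four blocks shaped
like the real descriptor families: 1024 binary (thresholded logits),
30 real, a 20-simplex and a 400-simplex (softmaxed logits). Truth labels
are emitted to a separate oracle table that pipeline stages never read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dtibalance.descriptors import (
    FEATURE_SET_WIDTHS,
    PairFeatureMatrix,
    _recipe_names,
)
from dtibalance.io_formats import (
    AMINO_ACIDS,
    DrugRecord,
    InteractionSet,
    Label,
    ProteinRecord,
)
from dtibalance.metrics import ConfusionCounts, MetricsReport, confusion_metrics

TRUTH_POSITIVE = "POSITIVE"
TRUTH_LATENT_POSITIVE = "LATENT_POSITIVE"
TRUTH_NEGATIVE = "TRUE_NEGATIVE"
TRUTH_BACKGROUND = "BACKGROUND"

# A pool of valid drug-like SMILES assigned to synthetic drug records, so
# the SMILES/FASTA mode exercises the real descriptor path.
SMILES_POOL: tuple[str, ...] = (
    "CCO", "CC(=O)O", "CC(=O)Oc1ccccc1C(=O)O", "c1ccccc1", "Cc1ccccc1",
    "CCN(CC)CC", "CC(C)O", "CCCCCC", "C1CCCCC1", "c1ccncc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "CN1C=NC2=C1C(=O)N(C(=O)N2C)C",
    "CC(=O)Nc1ccc(O)cc1", "Clc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
    "COc1ccccc1", "CC(N)C(=O)O", "NCCc1ccc(O)c(O)c1", "OCC(O)CO",
    "C(C(=O)O)N", "CC(C)(C)O", "CCOC(=O)C", "CCOCC", "CS(=O)C",
    "O=C(N)N", "NC(=O)c1ccccc1", "OC(=O)c1ccccc1", "CC#N", "C=CC=C",
    "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1", "c1ccoc1", "c1ccsc1",
    "C1CCNCC1", "C1CCOC1", "C1CCNC1", "O=C1CCCCC1", "OC1CCCCC1",
    "CC1=CC(=O)CC(C)(C)C1", "CC(=O)CC(=O)C", "CC(=O)C", "CCC(=O)O",
    "OCCO", "OCCN", "NCCN", "ClCCCl", "FC(F)(F)c1ccccc1",
    "Brc1ccccc1", "Ic1ccccc1", "O=[N+]([O-])c1ccccc1", "N#Cc1ccccc1",
    "CC(C)=CCCC(C)=CCO", "CC12CCC(CC1)C(C)(C)O2", "CC(C)C(=O)O",
    "CN(C)C=O", "CN(C)C", "O=S(=O)(O)O", "OP(=O)(O)O", "OC(=O)CCC(=O)O",
    "OC(=O)C=CC(=O)O", "CC(O)C(=O)O", "OC(CC(=O)O)C(=O)O",
    "Nc1ncnc2[nH]cnc12", "O=c1cc[nH]c(=O)[nH]1", "Cc1c[nH]c(=O)[nH]c1=O",
    "Nc1cc[nH]c(=O)n1", "OCC1OC(O)C(O)C(O)C1O", "CC(=O)NCCc1c[nH]c2ccccc12",
    "NCCc1c[nH]c2ccccc12", "NCCc1c[nH]cn1", "OC(=O)c1cc(O)c(O)c(O)c1",
    "COc1cc(C=O)ccc1O", "O=Cc1ccccc1", "OCc1ccccc1", "CCc1ccccc1",
    "C=Cc1ccccc1", "CC(C)c1ccccc1", "Cc1ccc(C)cc1", "Cc1cccc(C)c1",
    "Oc1ccc(O)cc1", "Oc1ccccc1O", "Nc1ccc(N)cc1", "Clc1ccc(Cl)cc1",
    "OC(=O)c1ccccc1O", "OC(=O)c1ccccc1N", "COC(=O)c1ccccc1",
    "CC(=O)c1ccccc1", "CNC(=O)c1ccccc1", "O=C(Nc1ccccc1)c1ccccc1",
    "C1CC2CCC1CC2", "C1CC2CC1CC2", "OC1CC2CCC1C2", "CC1CCCCC1",
    "CC1CCCC1", "CCC1CCCCC1", "CC(C)C1CCC(C)CC1", "O=C1OC(=O)c2ccccc12",
    "O=C1NC(=O)c2ccccc12", "c1ccc(-c2ccccc2)cc1", "C(c1ccccc1)c1ccccc1",
)

_BLOCK_DIMS = {"MORGAN": 1024, "CONSTITUTIONAL": 30, "AAC": 20, "DC": 400}
_RECIPE_BLOCKS = {
    "FS1": ("MORGAN", "AAC"),
    "FS2": ("MORGAN", "DC"),
    "FS3": ("CONSTITUTIONAL", "AAC"),
    "FS4": ("CONSTITUTIONAL", "DC"),
    "ALL": ("MORGAN", "CONSTITUTIONAL", "AAC", "DC"),
}


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 50
    n_proteins: int = 50
    positive_rate: float = 0.05
    latent_dim: int = 8
    negative_cluster_shift: float = 3.0
    noise_sd: float = 0.1
    seed: int = 0
    mode: str = "FEATURE_VECTORS"  # or SMILES_FASTA
    n_true_negatives: int | None = None  # default: one per positive
    n_latent_positives: int | None = None  # default: half the positive count

    def __post_init__(self) -> None:
        if not 0 < self.positive_rate < 0.5:
            raise ValueError("positive_rate must lie in (0, 0.5)")
        if self.negative_cluster_shift < 0:
            raise ValueError("negative_cluster_shift must be >= 0")
        if self.mode not in ("FEATURE_VECTORS", "SMILES_FASTA"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class SynthDataset:
    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    interactions: InteractionSet
    truth: dict[tuple[str, str], str]
    features: dict[str, PairFeatureMatrix] = field(default_factory=dict)

    @property
    def positives(self) -> InteractionSet:
        return InteractionSet(
            [(d, p, Label.POSITIVE) for d, p, lab in self.interactions
             if lab is Label.POSITIVE]
        )

    @property
    def unknowns(self) -> InteractionSet:
        return InteractionSet(
            [(d, p, Label.UNKNOWN) for d, p, lab in self.interactions
             if lab is Label.UNKNOWN]
        )

    def truth_pairs(self, truth_label: str) -> set[tuple[str, str]]:
        return {k for k, v in self.truth.items() if v == truth_label}


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate(cfg: SynthConfig) -> SynthDataset:
    """Generate a dataset; deterministic for a given config (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    n_pairs = cfg.n_drugs * cfg.n_proteins
    n_pos = int(round(cfg.positive_rate * n_pairs))
    if n_pos < 1:
        raise ValueError(
            f"positive_rate {cfg.positive_rate} yields no positives on a "
            f"{n_pairs}-pair grid"
        )
    n_latent = (
        cfg.n_latent_positives if cfg.n_latent_positives is not None else n_pos // 2
    )
    n_neg = cfg.n_true_negatives if cfg.n_true_negatives is not None else n_pos
    if n_pos + n_latent + n_neg > n_pairs:
        raise ValueError("planted classes exceed the pair grid")

    drug_ids = [f"D{i:04d}" for i in range(cfg.n_drugs)]
    prot_ids = [f"P{j:04d}" for j in range(cfg.n_proteins)]
    drugs = [
        DrugRecord(did, SMILES_POOL[i % len(SMILES_POOL)])
        for i, did in enumerate(drug_ids)
    ]
    proteins = [
        ProteinRecord(
            pid,
            "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(60, 200)))),
        )
        for pid in prot_ids
    ]

    u = rng.standard_normal((cfg.n_drugs, cfg.latent_dim))
    v = rng.standard_normal((cfg.n_proteins, cfg.latent_dim))
    score = (u @ v.T) / np.sqrt(cfg.latent_dim)  # ~ N(0, 1) entries

    flat = score.ravel()
    order = np.argsort(-flat, kind="mergesort")
    pos_flat = order[:n_pos]
    latent_flat = order[n_pos : n_pos + n_latent]
    remainder = order[n_pos + n_latent :]
    neg_flat = rng.choice(remainder, size=n_neg, replace=False)

    truth: dict[tuple[str, str], str] = {}
    status = np.full(n_pairs, TRUTH_BACKGROUND, dtype=object)
    status[pos_flat] = TRUTH_POSITIVE
    status[latent_flat] = TRUTH_LATENT_POSITIVE
    status[neg_flat] = TRUTH_NEGATIVE

    pairs = []
    keys: list[tuple[str, str]] = []
    for idx in range(n_pairs):
        i, j = divmod(idx, cfg.n_proteins)
        key = (drug_ids[i], prot_ids[j])
        keys.append(key)
        truth[key] = str(status[idx])
        label = Label.POSITIVE if status[idx] == TRUTH_POSITIVE else Label.UNKNOWN
        pairs.append((*key, label))
    interactions = InteractionSet(pairs)

    features = _embed_features(cfg, rng, u, v, score, status, keys)
    return SynthDataset(drugs, proteins, interactions, truth, features)


def _embed_features(
    cfg: SynthConfig,
    rng: np.random.Generator,
    u: np.ndarray,
    v: np.ndarray,
    score: np.ndarray,
    status: np.ndarray,
    keys: list[tuple[str, str]],
) -> dict[str, PairFeatureMatrix]:
    """Project latent structure into the four descriptor-shaped blocks."""
    d = cfg.latent_dim
    n_pairs = len(keys)
    s_flat = score.ravel()
    is_neg = (status == TRUTH_NEGATIVE).astype(float)
    is_pos = status == TRUTH_POSITIVE

    # Affinity excess above the positive threshold: positives spread along
    # the manifold direction, everything else (latent positives included)
    # sits at the manifold base. Displacements are per-coordinate so the
    # planted signal keeps pace with block width.
    threshold = s_flat[is_pos].min() if is_pos.any() else s_flat.max()
    excess = np.maximum(s_flat - threshold, 0.0)

    blocks: dict[str, np.ndarray] = {}
    for kind, width in _BLOCK_DIMS.items():
        w_u = rng.standard_normal((d, width)) / np.sqrt(d)
        w_v = rng.standard_normal((d, width)) / np.sqrt(d)
        h_pos = rng.choice((-0.5, 0.5), size=width)
        h_neg = rng.choice((-0.5, 0.5), size=width)

        drug_part = u @ w_u  # n_drugs x width
        prot_part = v @ w_v  # n_proteins x width
        i_idx = np.repeat(np.arange(cfg.n_drugs), cfg.n_proteins)
        j_idx = np.tile(np.arange(cfg.n_proteins), cfg.n_drugs)
        logits = 0.3 * (drug_part[i_idx] + prot_part[j_idx])
        logits += np.outer(excess, h_pos)
        logits -= cfg.negative_cluster_shift * np.outer(is_neg, h_neg)
        logits += cfg.noise_sd * rng.standard_normal((n_pairs, width))

        if kind == "MORGAN":
            blocks[kind] = (logits > 0).astype(float)
        elif kind == "CONSTITUTIONAL":
            blocks[kind] = logits
        else:
            blocks[kind] = _softmax(logits)

    out: dict[str, PairFeatureMatrix] = {}
    for fs_id, parts in _RECIPE_BLOCKS.items():
        matrix = np.hstack([blocks[k] for k in parts])
        assert matrix.shape == (n_pairs, FEATURE_SET_WIDTHS[fs_id])
        out[fs_id] = PairFeatureMatrix(fs_id, list(keys), matrix, _recipe_names(fs_id))
    return out


def subset_features(
    matrix: PairFeatureMatrix, keys: list[tuple[str, str]]
) -> PairFeatureMatrix:
    """Rows of a pair feature matrix restricted (and reordered) to ``keys``."""
    pos = {key: i for i, key in enumerate(matrix.pair_keys)}
    try:
        rows = [pos[key] for key in keys]
    except KeyError as exc:
        raise KeyError(f"pair {exc.args[0]} not present in feature matrix") from None
    return PairFeatureMatrix(
        matrix.feature_set_id,
        list(keys),
        matrix.matrix[rows],
        list(matrix.feature_names),
    )


def write_truth(truth: dict[tuple[str, str], str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\ttruth\n")
        for (d, p), lab in truth.items():
            fh.write(f"{d}\t{p}\t{lab}\n")


def read_truth(path: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {(r.drug_id, r.protein_id): r.truth for r in df.itertuples(index=False)}


def truth_report(
    predicted: list[tuple[str, str]],
    truth: dict[tuple[str, str], str] | str | Path,
    target_label: str = TRUTH_NEGATIVE,
) -> MetricsReport:
    """Precision/recall of a predicted pair set against the planted labels."""
    if not isinstance(truth, dict):
        truth = read_truth(truth)
    missing = [k for k in predicted if k not in truth]
    if missing:
        raise KeyError(f"oracle is missing evaluated pair(s): {missing[:3]}")
    predicted_set = set(predicted)
    if not predicted_set:
        warnings.warn("empty prediction set; precision reported as 0", stacklevel=2)
    tp = fp = fn = tn = 0
    for key, lab in truth.items():
        hit = key in predicted_set
        planted = lab == target_label
        tp += hit and planted
        fp += hit and not planted
        fn += planted and not hit
        tn += (not hit) and (not planted)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
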