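"""Chemical-space coverage analysis.

Pipeline: represent structures as numeric descriptors, prune descriptors that
are near-constant (diversity below a floor) or redundant (pairwise Pearson r²
above a ceiling), reduce with PCA to the number of components covering a
target variance, and embed in 2-D with t-SNE for visual comparison of
chemical sets.  Binary chemotype matrices support frequency comparison across
labelled sets, and stratified random sampling implements category-balanced
chemical shortlisting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .errors import DataError, InsufficientDataError, ParameterError

logger = logging.getLogger("toxtoolbox")


@dataclass
class DescriptorMatrix:
    """Items × descriptors numeric matrix with optional per-item set labels."""

    items: list[str]
    descriptors: list[str]
    values: np.ndarray
    set_label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.items) != len(set(self.items)):
            raise DataError("duplicated item identifiers in descriptor matrix")
        if self.values.shape != (len(self.items), len(self.descriptors)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.items)} items x {len(self.descriptors)} descriptors"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("descriptor matrix contains non-finite entries")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptors.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.items, columns=self.descriptors)


@dataclass
class ChemotypeMatrix:
    """Items × chemotypes binary matrix with per-item set labels."""

    items: list[str]
    chemotypes: list[str]
    values: np.ndarray
    set_label: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise DataError("chemotype matrix entries must be 0/1")
        self.values = self.values.astype(int)


@dataclass(frozen=True)
class PruneConfig:
    """Descriptor-pruning criteria: maximum tolerated pairwise Pearson r²
    and minimum accepted diversity."""

    r2_max: float = 0.8
    diversity_min: float = 0.3

    def __post_init__(self):
        if not (0 < self.r2_max <= 1 and 0 < self.diversity_min <= 1):
            raise ParameterError("r2_max and diversity_min must lie in (0, 1]")


def diversity_fraction_nonmodal(column: np.ndarray) -> float:
    """Default diversity scorer: fraction of items taking a non-modal value.

    Values are compared after rounding to 6 significant figures so that
    numerically indistinguishable entries count as one level; a constant
    column scores 0.
    """
    col = np.asarray(column, dtype=float)
    rounded = np.array([float(f"{v:.6g}") for v in col])
    _, counts = np.unique(rounded, return_counts=True)
    return 1.0 - counts.max() / len(rounded)


def prune_descriptors(
    m: DescriptorMatrix,
    cfg: PruneConfig = PruneConfig(),
    diversity_scorer: Callable[[np.ndarray], float] = diversity_fraction_nonmodal,
) -> tuple[DescriptorMatrix, list[dict]]:
    """Two-rule descriptor pruning with a removal log.

    Rule 1 removes every descriptor whose diversity score falls below
    ``cfg.diversity_min``.  Rule 2 scans the survivors in input column order
    and greedily removes any whose Pearson r² with an already-retained
    descriptor exceeds ``cfg.r2_max`` (keep-first-seen); the log records the
    retained partner for each correlation removal.
    """
    if len(m.items) < 2:
        raise InsufficientDataError("descriptor pruning needs at least 2 items")
    removal_log: list[dict] = []

    survivors: list[int] = []
    for j, name in enumerate(m.descriptors):
        score = diversity_scorer(m.values[:, j])
        if score < cfg.diversity_min:
            removal_log.append({"descriptor": name, "reason": "diversity", "score": score})
        else:
            survivors.append(j)

    retained: list[int] = []
    for j in survivors:
        partner = None
        for k in retained:
            r = _pearson(m.values[:, j], m.values[:, k])
            if r * r > cfg.r2_max:
                partner = k
                break
        if partner is not None:
            removal_log.append(
                {
                    "descriptor": m.descriptors[j],
                    "reason": "correlation",
                    "retained_partner": m.descriptors[partner],
                    "r2": _pearson(m.values[:, j], m.values[:, partner]) ** 2,
                }
            )
        else:
            retained.append(j)

    pruned = DescriptorMatrix(
        items=list(m.items),
        descriptors=[m.descriptors[j] for j in retained],
        values=m.values[:, retained],
        set_label=dict(m.set_label),
    )
    return pruned, removal_log


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PCAResult:
    scores: np.ndarray           # items x n_components
    explained_variance_ratio: np.ndarray  # over all fitted components
    n_components: int


def reduce_pca(
    m: DescriptorMatrix,
    variance_target: float = 0.95,
    standardize: bool = True,
) -> PCAResult:
    """PCA to the smallest number of components reaching ``variance_target``.

    Columns are standardized (zero mean, unit variance) by default; a
    zero-variance column surviving pruning is a numerical-guard error.
    """
    if not (0 < variance_target <= 1):
        raise ParameterError("variance_target must lie in (0, 1]")
    X = m.values.astype(float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [m.descriptors[j] for j in np.flatnonzero(sd == 0)]
            raise DataError(f"zero-variance descriptor(s) reached PCA: {bad}")
        X = X / sd
    pca = PCA()
    scores_full = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    n_comp = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, scores_full.shape[1])
    return PCAResult(
        scores=scores_full[:, :n_comp],
        explained_variance_ratio=evr,
        n_components=n_comp,
    )


def embed_2d(
    scores: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> np.ndarray:
    """Deterministic 2-D t-SNE embedding of component scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ParameterError("scores must be a 2-D array")
    if scores.shape[0] < 3 * perplexity:
        raise ParameterError(
            f"t-SNE with perplexity {perplexity} needs at least {int(3 * perplexity)} "
            f"items (got {scores.shape[0]})"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate="auto",
        max_iter=n_iter,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(scores)


def chemotype_frequencies(
    cm: ChemotypeMatrix,
    top_k: int = 33,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-set frequency table of the pooled union's ``top_k`` chemotypes.

    Frequency is the percentage of a set's items possessing the chemotype.
    Ranking is by pooled frequency with alphabetical tie-break.  Also returns
    the number of distinct chemotypes present in each set.
    """
    if not cm.set_label:
        raise DataError("chemotype matrix has no set labels")
    sets = sorted(set(cm.set_label.values()))
    item_index = {it: i for i, it in enumerate(cm.items)}
    members = {s: [item_index[it] for it in cm.items if cm.set_label.get(it) == s] for s in sets}
    for s, idx in members.items():
        if not idx:
            raise DataError(f"set label {s!r} has no items")

    pooled_freq = cm.values.mean(axis=0)
    order = sorted(
        range(len(cm.chemotypes)),
        key=lambda j: (-pooled_freq[j], cm.chemotypes[j]),
    )[: min(top_k, len(cm.chemotypes))]

    rows = []
    for j in order:
        row = {"chemotype": cm.chemotypes[j], "pooled_pct": 100.0 * pooled_freq[j]}
        for s in sets:
            row[s] = 100.0 * cm.values[members[s], j].mean()
        rows.append(row)
    table = pd.DataFrame(rows)

    distinct = {
        s: int((cm.values[members[s], :].sum(axis=0) > 0).sum()) for s in sets
    }
    return table, distinct


def stratified_select(
    candidates: Mapping[str, str],
    categories: Sequence[str],
    n_per_category: int = 40,
    seed: int = 0,
) -> list[str]:
    """Uniform random sample without replacement of up to ``n_per_category``
    items from each requested category; deterministic for a fixed seed.

    A category smaller than the quota contributes all of its members, so the
    shortlist size is the sum of min(quota, category size).
    """
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[str]] = {}
    for item, cat in candidates.items():
        by_cat.setdefault(cat, []).append(item)
    shortlist: list[str] = []
    for cat in categories:
        pool = sorted(by_cat.get(cat, []))
        if not pool:
            raise DataError(f"requested category {cat!r} has no candidates")
        take = min(n_per_category, len(pool))
        chosen = rng.choice(len(pool), size=take, replace=False)
        shortlist.extend(pool[i] for i in sorted(chosen))
    return shortlist


# ---------------------------------------------------------------------------
# Descriptor providers
# ---------------------------------------------------------------------------

def rdkit_descriptor_provider(
    smiles: Sequence[str],
    items: Optional[Sequence[str]] = None,
) -> DescriptorMatrix:
    """Built-in provider computing a small standard physico-chemical set with
    RDKit (MolWt, MolLogP, TPSA, H-bond donors/acceptors, rotatable bonds,
    ring count, fraction Csp3, heavy atoms, molar refractivity).

    Structures are parsed as given — no desalting — and any unparsable SMILES
    raises DataError.  Any callable mapping SMILES to a DescriptorMatrix can
    stand in for this provider.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    funcs = {
        "MolWt": Descriptors.MolWt,
        "MolLogP": Crippen.MolLogP,
        "TPSA": rdMolDescriptors.CalcTPSA,
        "NumHDonors": rdMolDescriptors.CalcNumHBD,
        "NumHAcceptors": rdMolDescriptors.CalcNumHBA,
        "NumRotatableBonds": rdMolDescriptors.CalcNumRotatableBonds,
        "RingCount": rdMolDescriptors.CalcNumRings,
        "FractionCSP3": rdMolDescriptors.CalcFractionCSP3,
        "HeavyAtomCount": lambda m: m.GetNumHeavyAtoms(),
        "MolMR": Crippen.MolMR,
    }
    if items is None:
        items = [f"item{i}" for i in range(len(smiles))]
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DataError(f"unparsable SMILES: {smi!r}")
        rows.append([f(mol) for f in funcs.values()])
    return DescriptorMatrix(
        items=list(items),
        descriptors=list(funcs),
        values=np.asarray(rows, dtype=float),
    )


def dedupe_structures(smiles: Sequence[str]) -> list[str]:
    """Remove duplicate structures by canonicalized structure text.

    Mixtures are kept and salts are not stripped; duplication is judged on
    the canonical SMILES of the full input structure.
    """
    from rdkit import Chem

    seen: set[str] = set()
    out: list[str] = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        key = Chem.MolToSmiles(mol) if mol is not None else smi
        if key not in seen:
            seen.add(key)
            out.append(smi)
    return out
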