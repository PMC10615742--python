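"""Brain lipidomics: differential abundance gated on effect size, category
enrichment, and ordination.

The analysis takes a quantified lipid x sample abundance table (e.g. 464
lipids across 26 classes and 29 fatty acids from targeted LC-MS/MS) and asks
which lipids, lipid classes and acyl chains distinguish experimental groups.
A lipid counts as *differential* only when it clears both a significance
gate and a substantive-effect gate (default raw P < 0.05 and |Cohen's d| >
0.8); enrichment of classes and fatty acids among the differential lipids is
then scored with Fisher's exact test (phi effect size) against the full
tested background.  Supervised structure is summarized with OPLS-DA, whose
top-|loading| fraction (default the top 1%) names the individual molecules
carrying the group difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .stats import adjust_pvalues, fishers_exact_2x2, two_way_anova

__all__ = [
    "LipidTable",
    "DifferentialGate",
    "OrdinationResult",
    "read_lipid_table",
    "preprocess",
    "differential_lipids",
    "class_enrichment",
    "fatty_acid_enrichment",
    "pca",
    "hierarchical_clustering",
    "linkage_to_newick",
    "cut_clusters",
    "oplsda",
    "oplsda_q2y",
    "oplsda_permutation_q2y",
    "distance_anova",
]


@dataclass
class LipidTable:
    """Lipid x sample abundances with annotations.

    ``abundance``: DataFrame (lipid_id x sample_id), nonnegative.
    ``lipids``: DataFrame indexed by lipid_id with columns ``lipid_class``
    and ``acyl_chains`` (list of "C:D" strings).
    ``samples``: DataFrame indexed by sample_id with factor columns
    (genotype, diet, sex, ...).
    """

    abundance: pd.DataFrame
    lipids: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundance.index.duplicated().any():
            raise ValueError("duplicate lipid_id in abundance matrix")
        if not self.abundance.index.equals(self.lipids.index):
            raise ValueError("lipid annotation does not match abundance rows")
        if not self.abundance.columns.equals(self.samples.index):
            raise ValueError("sample metadata does not match abundance columns")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.lipids["acyl_chains"].map(len).min() < 1:
            raise ValueError("every lipid needs at least one acyl chain")

    @property
    def n_lipids(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def classes(self) -> pd.Series:
        return self.lipids["lipid_class"]

    def fatty_acids(self) -> list[str]:
        return sorted({c for chains in self.lipids["acyl_chains"] for c in chains})

    def subset_samples(self, mask) -> "LipidTable":
        cols = self.samples.index[mask]
        return LipidTable(
            abundance=self.abundance[cols],
            lipids=self.lipids,
            samples=self.samples.loc[cols],
        )

    def write(self, prefix) -> None:
        """Write <prefix>.abundance.tsv / .annotations.tsv / .samples.tsv."""
        prefix = str(prefix)
        self.abundance.to_csv(prefix + ".abundance.tsv", sep="\t")
        ann = self.lipids.copy()
        ann["acyl_chains"] = ann["acyl_chains"].map(";".join)
        ann.to_csv(prefix + ".annotations.tsv", sep="\t")
        self.samples.to_csv(prefix + ".samples.tsv", sep="\t")


KNOWN_CLASSES = {
    "PC", "PE", "PE(P)", "PE(O)", "PS", "PI", "PG", "PA", "LPC", "LPE",
    "LPS", "LPI", "LPG", "LPA", "SM", "Cer", "HexCer", "SHexCer", "ST",
    "DG", "TG", "MG", "CL", "BMP", "CE", "FA", "GM3", "ACar", "CoQ",
}


def read_lipid_table(abundance_path, annotation_path, metadata_path) -> LipidTable:
    """Assemble a LipidTable from TSV/CSV files.

    ``annotation``: columns lipid_id, lipid_class, acyl_chains
    (semicolon-separated "C:D").  Unknown class abbreviations pass through
    with a warning; mismatched lipid or sample ids are errors.
    """

    def _read(path):
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        return pd.read_csv(path, sep=sep, index_col=0)

    abundance = _read(abundance_path)
    ann = _read(annotation_path)
    meta = _read(metadata_path)
    if abundance.index.duplicated().any():
        dup = abundance.index[abundance.index.duplicated()][0]
        raise ValueError(f"duplicated lipid_id: {dup!r}")
    if set(abundance.index) != set(ann.index):
        raise ValueError("lipid_ids differ between abundance and annotation files")
    if set(abundance.columns) != set(meta.index):
        raise ValueError("sample_ids differ between abundance and metadata files")
    ann = ann.loc[abundance.index]
    meta = meta.loc[abundance.columns]
    ann = ann.copy()
    ann["acyl_chains"] = ann["acyl_chains"].map(lambda s: str(s).split(";"))
    unknown = set(ann["lipid_class"]) - KNOWN_CLASSES
    if unknown:
        warnings.warn(
            f"unknown lipid class abbreviation(s): {sorted(unknown)}", stacklevel=2
        )
    n_zero = int((abundance.to_numpy() <= 0).sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero/missing abundance entries", stacklevel=2)
    return LipidTable(abundance=abundance, lipids=ann, samples=meta)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(table: LipidTable, log: bool = True, scale: bool = False) -> pd.DataFrame:
    """Log2(x + pseudocount) with a per-lipid pseudocount of half the
    minimum positive abundance (raw values with ``log=False``); optional
    unit-variance scaling per lipid (for ordination)."""
    x = table.abundance.to_numpy(dtype=float)
    if log:
        pos_min = np.where(x > 0, x, np.inf).min(axis=1)
        pos_min = np.where(np.isfinite(pos_min), pos_min, 1.0)
        x = np.log2(x + 0.5 * pos_min[:, None])
    if scale:
        sd = x.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(x, index=table.abundance.index, columns=table.abundance.columns)


# ---------------------------------------------------------------------------
# differential abundance


@dataclass(frozen=True)
class DifferentialGate:
    """Joint significance/effect gate: selected <=> p < p_max and |d| > d_min."""

    p_max: float = 0.05
    d_min: float = 0.8


def differential_lipids(
    table: LipidTable,
    factor: str,
    level_a: str,
    level_b: str,
    gate: DifferentialGate | None = None,
    variant: str = "welch",
    log: bool = True,
) -> pd.DataFrame:
    """Per-lipid two-sample t-test with signed Cohen's d and the joint gate.

    Returns a DataFrame indexed by lipid_id with columns t, p, p_adj (BH
    across lipids), d (signed, level_a minus level_b), selected, and
    testable (False for zero-pooled-variance lipids, which are excluded
    from selection and the BH family).
    """
    gate = gate or DifferentialGate()
    if factor not in table.samples.columns:
        raise ValueError(f"unknown sample factor: {factor!r}")
    in_a = (table.samples[factor] == level_a).to_numpy()
    in_b = (table.samples[factor] == level_b).to_numpy()
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need >= 2 samples per level")
    x = preprocess(table, log=log).to_numpy()
    xa, xb = x[:, in_a], x[:, in_b]
    na, nb = xa.shape[1], xb.shape[1]
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    testable = pooled > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(xa, xb, axis=1, equal_var=(variant == "student"))
        d = (xa.mean(axis=1) - xb.mean(axis=1)) / np.sqrt(pooled)
    p = np.asarray(res.pvalue, dtype=float)
    out = pd.DataFrame(
        {
            "t": np.asarray(res.statistic, dtype=float),
            "p": p,
            "d": d,
            "testable": testable,
        },
        index=table.abundance.index,
    )
    out["p_adj"] = np.nan
    out.loc[testable, "p_adj"] = adjust_pvalues(p[testable], "bh")
    out["selected"] = testable & (p < gate.p_max) & (np.abs(d) > gate.d_min)
    if (~testable).any():
        warnings.warn(
            f"{int((~testable).sum())} zero-variance lipid(s) excluded", stacklevel=2
        )
    return out


# ---------------------------------------------------------------------------
# enrichment


def _enrich(categories: dict[str, np.ndarray], selected: np.ndarray) -> pd.DataFrame:
    rows = []
    for name, member in categories.items():
        a = int((selected & member).sum())
        b = int((selected & ~member).sum())
        c = int((~selected & member).sum())
        d = int((~selected & ~member).sum())
        res = fishers_exact_2x2([[a, b], [c, d]])
        rows.append(
            {
                "category": name,
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": res.extra["odds_ratio"],
                "p": res.p_value,
                "phi": res.effect.signed_value,
                "phi_defined": res.extra["phi_defined"],
            }
        )
    out = pd.DataFrame(rows).set_index("category").sort_values("p")
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    return out


def _aligned_selection(results: pd.DataFrame, table: LipidTable) -> np.ndarray:
    """Selection mask over the testable background, aligned to table rows."""
    res = results.reindex(table.abundance.index)
    testable = res["testable"].fillna(False).to_numpy(dtype=bool)
    selected = res["selected"].fillna(False).to_numpy(dtype=bool)
    return selected[testable], testable


def class_enrichment(results: pd.DataFrame, table: LipidTable) -> pd.DataFrame:
    """Per-lipid-class 2x2 Fisher enrichment of the selected set against the
    testable background; BH-adjusted p across classes alongside raw p."""
    selected, testable = _aligned_selection(results, table)
    classes = table.classes().to_numpy()[testable]
    cats = {
        cls: classes == cls
        for cls in pd.unique(classes)
        if (classes == cls).sum() > 0
    }
    return _enrich(cats, selected)


def fatty_acid_enrichment(results: pd.DataFrame, table: LipidTable) -> pd.DataFrame:
    """Per-fatty-acid Fisher enrichment.  Membership is lipid-level and
    set-valued: a lipid belongs to each *distinct* chain it carries (two
    16:0 chains still count once for 16:0)."""
    selected, testable = _aligned_selection(results, table)
    chains_per_lipid = [set(ch) for ch in table.lipids["acyl_chains"][testable]]
    cats = {
        fa: np.array([fa in ch for ch in chains_per_lipid])
        for fa in sorted({c for ch in chains_per_lipid for c in ch})
    }
    return _enrich(cats, selected)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    kind: str  # "PCA" or "OPLSDA"
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # lipids x components
    explained_variance: np.ndarray
    extra: dict = field(default_factory=dict)


def pca(table: LipidTable, n_components: int = 2, log: bool = True, scale: bool = True) -> OrdinationResult:
    """PCA of preprocessed profiles (samples as observations)."""
    x = preprocess(table, log=log, scale=scale).to_numpy().T  # samples x lipids
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components, rank allows {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    comp = [f"PC{i+1}" for i in range(n_components)]
    return OrdinationResult(
        kind="PCA",
        scores=pd.DataFrame(scores, index=table.abundance.columns, columns=comp),
        loadings=pd.DataFrame(
            model.components_.T, index=table.abundance.index, columns=comp
        ),
        explained_variance=model.explained_variance_ratio_,
        extra={"mean": model.mean_},
    )


def hierarchical_clustering(
    table: LipidTable, metric: str = "euclidean", method: str = "ward",
    log: bool = True, scale: bool = False,
) -> dict:
    """Agglomerative clustering of samples on preprocessed profiles.

    Returns the scipy linkage matrix plus sample labels; ties broken
    deterministically by sample order (scipy's canonical ordering).
    """
    x = preprocess(table, log=log, scale=scale).to_numpy().T
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in preprocessed data")
    link = hierarchy.linkage(x, method=method, metric=metric)
    return {"linkage": link, "labels": list(table.abundance.columns)}


def _tree_to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id].replace(" ", "_")
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)
    return _tree_to_newick(tree, labels) + ";"


def cut_clusters(linkage: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def _opls_fit(x: np.ndarray, y: np.ndarray, n_orthogonal: int) -> dict:
    """O-PLS deflation on centered X and y: strip label-orthogonal
    components, then a single predictive PLS component."""
    t_orth, p_orth, w_orth = [], [], []
    for _ in range(n_orthogonal):
        w = x.T @ y
        w /= np.linalg.norm(w)
        t = x @ w
        p = x.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            break  # no orthogonal variation left
        wo /= norm
        to = x @ wo
        po = x.T @ to / (to @ to)
        x = x - np.outer(to, po)
        t_orth.append(to)
        p_orth.append(po)
        w_orth.append(wo)
    w = x.T @ y
    w /= np.linalg.norm(w)
    t_pred = x @ w
    p_pred = x.T @ t_pred / (t_pred @ t_pred)
    q = float(y @ t_pred / (t_pred @ t_pred))
    return {
        "w_pred": w, "t_pred": t_pred, "p_pred": p_pred, "q": q,
        "t_orth": t_orth, "p_orth": p_orth, "w_orth": w_orth,
    }


def _opls_predict(fit: dict, x_new: np.ndarray) -> np.ndarray:
    """Predict centered y for new (centered) rows: remove the orthogonal
    variation, then project on the predictive weights."""
    x_new = np.atleast_2d(x_new).copy()
    for wo, po in zip(fit["w_orth"], fit["p_orth"]):
        to = x_new @ wo
        x_new = x_new - np.outer(to, po)
    return (x_new @ fit["w_pred"]) * fit["q"]


def oplsda(
    table: LipidTable,
    factor: str,
    positive_level: str,
    n_orthogonal: int = 1,
    top_fraction: float = 0.01,
    log: bool = True,
    scale: bool = True,
) -> OrdinationResult:
    """Orthogonal PLS discriminant analysis for a binary class factor.

    The O-PLS deflation removes ``n_orthogonal`` components of X-variation
    orthogonal to the class vector before a final single-component PLS fit,
    so one predictive component carries all the label-correlated variation.
    Lipids are ranked by |predictive loading|; the top
    ceil(top_fraction * n_lipids) are flagged (1% of 464 lipids = 5).
    With ``n_orthogonal=0`` this reduces to one-component PLS-DA.
    """
    labels = table.samples[factor]
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("OPLS-DA needs exactly 2 class levels")
    if (labels == uniq[0]).sum() < 3 or (labels == uniq[1]).sum() < 3:
        raise ValueError("OPLS-DA needs >= 3 samples per class")
    y = np.where(labels.to_numpy() == positive_level, 1.0, -1.0)
    if np.ptp(y) == 0:
        raise ValueError("constant class label")
    y = y - y.mean()
    x = preprocess(table, log=log, scale=scale).to_numpy().T  # samples x lipids
    x_mean = x.mean(axis=0)
    x = x - x_mean
    ss_x_total = float((x**2).sum())

    fit = _opls_fit(x, y, n_orthogonal)
    t_orth_list, t_pred = fit["t_orth"], fit["t_pred"]
    p_pred, q = fit["p_pred"], fit["q"]
    y_hat = q * t_pred
    r2y = 1.0 - float(((y - y_hat) ** 2).sum() / (y**2).sum())

    comp = ["predictive"] + [f"orthogonal{i+1}" for i in range(len(t_orth_list))]
    scores = np.column_stack([t_pred] + t_orth_list)
    loadings = np.column_stack([p_pred] + fit["p_orth"])
    explained = np.array(
        [float((s @ s) * (l @ l)) / ss_x_total for s, l in zip(scores.T, loadings.T)]
    )
    n_top = math.ceil(top_fraction * table.n_lipids)
    order = np.argsort(-np.abs(p_pred))
    top = np.zeros(table.n_lipids, dtype=bool)
    top[order[:n_top]] = True
    load_df = pd.DataFrame(loadings, index=table.abundance.index, columns=comp)
    load_df["top"] = top
    return OrdinationResult(
        kind="OPLSDA",
        scores=pd.DataFrame(scores, index=table.abundance.columns, columns=comp),
        loadings=load_df,
        explained_variance=explained,
        extra={
            "weights_predictive": fit["w_pred"],
            "r2y": r2y,
            "n_top": n_top,
            "top_lipids": list(table.abundance.index[top]),
            "positive_level": positive_level,
        },
    )


def oplsda_q2y(
    table: LipidTable,
    factor: str,
    positive_level: str,
    n_orthogonal: int = 1,
    log: bool = True,
    scale: bool = True,
    y: np.ndarray | None = None,
) -> float:
    """Leave-one-out cross-validated Q2Y of the OPLS-DA model.

    With many more variables than samples the fitted R2Y saturates near 1
    whatever the labels, so predictive performance is judged by LOO Q2Y
    (1 - PRESS/SS); chance-level models give Q2Y <= 0.
    """
    labels = table.samples[factor].to_numpy()
    if y is None:
        y = np.where(labels == positive_level, 1.0, -1.0)
    x_all = preprocess(table, log=log, scale=scale).to_numpy().T
    n = x_all.shape[0]
    press = 0.0
    yc_all = y - y.mean()
    for i in range(n):
        keep = np.arange(n) != i
        x = x_all[keep]
        x_mean = x.mean(axis=0)
        yk = y[keep]
        yc = yk - yk.mean()
        fit = _opls_fit(x - x_mean, yc, n_orthogonal)
        pred = _opls_predict(fit, x_all[i] - x_mean)[0] + yk.mean()
        press += (y[i] - pred) ** 2
    return 1.0 - press / float((yc_all**2).sum())


def oplsda_permutation_q2y(
    table: LipidTable,
    factor: str,
    positive_level: str,
    n_permutations: int = 100,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Label-permutation reference distribution for the LOO Q2Y."""
    rng = np.random.default_rng(seed)
    observed = oplsda_q2y(table, factor, positive_level, **kwargs)
    labels = table.samples[factor].to_numpy()
    y = np.where(labels == positive_level, 1.0, -1.0)
    perm = [
        oplsda_q2y(table, factor, positive_level, y=rng.permutation(y), **kwargs)
        for _ in range(n_permutations)
    ]
    return {"q2y": observed, "permuted": np.array(perm)}


# ---------------------------------------------------------------------------
# distance ANOVA


def distance_anova(
    table: LipidTable,
    factor_a: str = "genotype",
    factor_b: str = "diet",
    reference_level: str | None = None,
    log: bool = True,
    scale: bool = True,
):
    """Two-way ANOVA of per-sample Euclidean distances between lipid
    profiles and a reference centroid.

    The reference is the centroid of the ``reference_level`` group of
    ``factor_a`` (the control genotype; first-encountered level when None),
    so displacement of the other group registers as a factor_a effect.
    ``reference_level='grand'`` uses the grand centroid instead — a pure
    dispersion measure that is blind to a balanced two-group displacement.
    """
    x = preprocess(table, log=log, scale=scale).to_numpy().T
    levels_a = table.samples[factor_a].to_numpy()
    if reference_level is None:
        reference_level = levels_a[0]
    if reference_level == "grand":
        centroid = x.mean(axis=0)
    else:
        mask = levels_a == reference_level
        if not mask.any():
            raise ValueError(f"no samples at reference level {reference_level!r}")
        centroid = x[mask].mean(axis=0)
    dist = np.linalg.norm(x - centroid, axis=1)
    if np.allclose(dist, 0):
        raise ValueError("all samples identical: distances degenerate")
    return two_way_anova(
        dist,
        table.samples[factor_a].to_numpy(),
        table.samples[factor_b].to_numpy(),
        interaction=False,
    )
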