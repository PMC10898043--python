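"""cfDNA cohort simulation and the leave-one-out cancer detection model.

The model mirrors a standard cfDNA methylation classifier: strict coverage
QC (autosomal CpGs at depth > 100x in > 80% of samples; samples missing
> 20% of those sites excluded), a promoter-locality + variance (>= 0.009)
feature prefilter, then leave-one-out cross-validation where each fold
re-ranks CpGs by a two-sided Welch t statistic on the training samples
only, trains an L2 logistic regression on the top features, and scores the
held-out sample; the predicted probability is its tumor score.

The synthetic cohort mixes a shared normal methylome with a planted tumor
component at a chosen tumor fraction f, so BC samples shift by f x dbeta at
the informative CpGs — the circulating-tumor-DNA dilution that makes early
detection hard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .genome import MethylationProfile, ReferenceGenome
from .intervals import ElementAnnotation

BC, NBC = "BC", "NBC"


@dataclass
class MethylMatrix:
    """Sites x samples beta and depth matrices with site metadata and labels."""

    beta: pd.DataFrame          # sites x samples, NaN where depth == 0
    depth: pd.DataFrame         # sites x samples, integer
    sites: pd.DataFrame         # index = site id; columns chrom, pos, autosome
    labels: pd.Series           # sample -> {BC, NBC}

    def __post_init__(self) -> None:
        if not self.beta.shape == self.depth.shape:
            raise ValueError("beta and depth matrices must share dimensions")
        if not self.beta.index.equals(self.depth.index):
            raise ValueError("beta and depth site indices differ")
        if set(self.labels.unique()) - {BC, NBC}:
            raise ValueError("labels must be BC or NBC")

    @property
    def n_sites(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_sites(self, site_ids) -> "MethylMatrix":
        return MethylMatrix(self.beta.loc[site_ids], self.depth.loc[site_ids],
                            self.sites.loc[site_ids], self.labels)

    def subset_samples(self, sample_ids) -> "MethylMatrix":
        return MethylMatrix(self.beta[sample_ids], self.depth[sample_ids],
                            self.sites, self.labels.loc[sample_ids])

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(directory / "beta.tsv", sep="\t")
        self.depth.to_csv(directory / "depth.tsv", sep="\t")
        self.labels.rename("label").to_csv(directory / "labels.tsv", sep="\t")

    @classmethod
    def read(cls, beta_path, depth_path, labels_path) -> "MethylMatrix":
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        depth = pd.read_csv(depth_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0)["label"]
        sites = _sites_from_index(beta.index)
        return cls(beta, depth, sites, labels)


def _sites_from_index(index: pd.Index) -> pd.DataFrame:
    chroms, positions = [], []
    for site_id in index:
        chrom, pos = str(site_id).rsplit(":", 1)
        chroms.append(chrom)
        positions.append(int(pos))
    autosome = [c not in ("chrX", "chrY", "X", "Y") for c in chroms]
    return pd.DataFrame({"chrom": chroms, "pos": positions, "autosome": autosome},
                        index=index)


@dataclass
class CohortDesign:
    """Parameters of the synthetic two-group cfDNA cohort."""

    n_bc: int = 30
    n_nbc: int = 30
    tumor_fraction: float = 0.3
    n_informative_cpgs: int = 100
    effect_delta: float = 0.5
    depth: int = 200
    sample_jitter_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bc < 0 or self.n_nbc < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not (0.0 <= self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must be in [0, 1]")
        if not (0.0 <= self.effect_delta <= 1.0):
            raise ValueError("effect_delta must be in [0, 1]")


@dataclass
class ClassifierResult:
    scores: pd.Series           # per-sample tumor score in [0, 1]
    labels: pd.Series
    roc: pd.DataFrame           # columns fpr, tpr, threshold
    auc: float
    selected_features: dict[str, list[str]] = field(default_factory=dict)

    def youden_threshold(self) -> float:
        """Probability cutoff maximizing TPR - FPR on the pooled scores."""
        j = self.roc["tpr"] - self.roc["fpr"]
        return float(self.roc.loc[j.idxmax(), "threshold"])


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(design: CohortDesign, genome: ReferenceGenome,
                    tss: ElementAnnotation, profile: MethylationProfile,
                    tss_flank: int = 2000) -> MethylMatrix:
    """Simulate a BC/NBC cfDNA cohort over the genome's CpG sites.

    NBC betas scatter around the shared normal profile (per-sample Gaussian
    jitter plus binomial counting noise at the given depth). BC betas at the
    informative promoter CpGs are shifted to the tumor-fraction mixture
    (1-f) * normal + f * (normal +/- effect_delta), the shift directed away
    from the nearer beta boundary. Deterministic per seed.
    """
    rng = np.random.default_rng(design.seed)
    chrom = genome.chrom_names()[0]
    all_pos = np.array(profile.positions(chrom))
    normal = np.array([profile.beta(chrom, p) for p in all_pos])

    tss_pos = np.array([iv.start for iv in tss])
    near_tss = np.zeros(len(all_pos), dtype=bool)
    for t in tss_pos:
        near_tss |= (all_pos >= t - tss_flank) & (all_pos < t + tss_flank)
    candidates = np.flatnonzero(near_tss)
    if design.n_informative_cpgs > len(candidates):
        raise ValueError(
            f"requested {design.n_informative_cpgs} informative CpGs but only "
            f"{len(candidates)} promoter CpGs available")
    informative = rng.choice(candidates, size=design.n_informative_cpgs,
                             replace=False)

    shift_sign = np.where(normal < 0.5, 1.0, -1.0)
    tumor = normal.copy()
    tumor[informative] = np.clip(
        normal[informative] + shift_sign[informative] * design.effect_delta, 0, 1)
    bc_mean = (1 - design.tumor_fraction) * normal + design.tumor_fraction * tumor

    sample_ids = ([f"BC{i:03d}" for i in range(design.n_bc)]
                  + [f"NBC{i:03d}" for i in range(design.n_nbc)])
    labels = pd.Series([BC] * design.n_bc + [NBC] * design.n_nbc,
                       index=sample_ids, name="label")

    n_sites = len(all_pos)
    beta_obs = np.empty((n_sites, len(sample_ids)))
    depth_obs = np.empty((n_sites, len(sample_ids)), dtype=int)
    for j, sample in enumerate(sample_ids):
        mean = bc_mean if labels[sample] == BC else normal
        true_beta = np.clip(mean + rng.normal(0, design.sample_jitter_sd, n_sites),
                            0, 1)
        d = np.maximum(rng.poisson(design.depth, n_sites), 1)
        m = rng.binomial(d, true_beta)
        depth_obs[:, j] = d
        beta_obs[:, j] = m / d

    site_ids = [f"{chrom}:{p}" for p in all_pos]
    beta = pd.DataFrame(beta_obs, index=site_ids, columns=sample_ids)
    depth = pd.DataFrame(depth_obs, index=site_ids, columns=sample_ids)
    sites = _sites_from_index(beta.index)
    return MethylMatrix(beta, depth, sites, labels)


# ---------------------------------------------------------------------------
# QC and feature filters
# ---------------------------------------------------------------------------

def qc_filter(matrix: MethylMatrix, site_min_depth: int = 100,
              site_sample_frac: float = 0.8,
              sample_missing_frac: float = 0.2) -> tuple[MethylMatrix, dict]:
    """Coverage QC: sites first, then samples (order is part of the contract).

    Step 1 keeps autosomal CpGs at depth STRICTLY above ``site_min_depth``
    in STRICTLY more than ``site_sample_frac`` of samples. Step 2 excludes
    samples with strictly more than ``sample_missing_frac`` of the kept
    sites below ``site_min_depth``.
    """
    autosomal = matrix.sites["autosome"].to_numpy()
    frac_covered = (matrix.depth > site_min_depth).mean(axis=1).to_numpy()
    keep_sites = autosomal & (frac_covered > site_sample_frac)
    kept_ids = matrix.beta.index[keep_sites]
    report = {
        "sites_in": matrix.n_sites,
        "sites_kept": int(keep_sites.sum()),
        "sites_removed_non_autosomal": int((~autosomal).sum()),
        "sites_removed_low_coverage": int((autosomal & ~keep_sites).sum()),
        "samples_excluded": [],
    }
    if len(kept_ids) == 0:
        raise ValueError("no sites survive the coverage QC filter")

    depth_kept = matrix.depth.loc[kept_ids]
    missing_frac = (depth_kept < site_min_depth).mean(axis=0)
    keep_samples = missing_frac <= sample_missing_frac
    for sample in matrix.beta.columns[~keep_samples]:
        report["samples_excluded"].append(
            {"sample": sample,
             "reason": f"{missing_frac[sample]:.1%} of kept sites below "
                       f"{site_min_depth}x (limit {sample_missing_frac:.0%})"})
    kept_samples = matrix.beta.columns[keep_samples]
    if len(kept_samples) == 0:
        raise ValueError("all samples excluded by the coverage QC filter")
    return matrix.subset_sites(kept_ids).subset_samples(kept_samples), report


def feature_prefilter(matrix: MethylMatrix, tss: ElementAnnotation,
                      flank: int = 2000, var_min: float = 0.009) -> MethylMatrix:
    """Keep CpGs within TSS +/- flank whose across-sample beta variance
    (population variance, missing excluded) reaches ``var_min``."""
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    near = np.zeros(matrix.n_sites, dtype=bool)
    for iv in tss:
        near |= (chroms == iv.chrom) & (pos >= iv.start - flank) & (pos < iv.start + flank)
    if not near.any():
        raise ValueError(f"no CpGs within TSS +/- {flank} bp (locality filter)")
    variance = matrix.beta.var(axis=1, ddof=0, skipna=True).to_numpy()
    keep = near & (variance >= var_min)
    if not keep.any():
        raise ValueError(f"no CpGs with variance >= {var_min} (variance filter)")
    return matrix.subset_sites(matrix.beta.index[keep])


# ---------------------------------------------------------------------------
# Leave-one-out classifier
# ---------------------------------------------------------------------------

def _welch_rank(x_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """Features ordered by decreasing |Welch t| between the two classes."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = stats.ttest_ind(x_train[y_train == 1], x_train[y_train == 0],
                               equal_var=False, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    t[~np.isfinite(t)] = 0.0
    return np.argsort(-np.abs(t), kind="stable")


def loo_classify(matrix: MethylMatrix, n_features_select: int = 50,
                 C: float = 1.0, seed: int = 0) -> ClassifierResult:
    """Leave-one-out tumor scores with strictly in-fold feature selection.

    Each fold ranks the prefiltered CpGs by two-sided Welch t statistic on
    the training samples only, takes the top ``n_features_select``, imputes
    missing betas by the training-fold feature mean, fits an L2 logistic
    regression, and emits the held-out sample's predicted probability.
    """
    y = (matrix.labels == BC).astype(int).to_numpy()
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need at least 3 samples per class")
    x = matrix.beta.to_numpy().T  # samples x features
    samples = matrix.beta.columns
    feature_ids = matrix.beta.index

    scores = np.empty(len(samples))
    selected: dict[str, list[str]] = {}
    for i in range(len(samples)):
        train = np.ones(len(samples), dtype=bool)
        train[i] = False
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {samples[i]} leaves a single-class training set")
        x_tr = x[train]
        order = _welch_rank(x_tr, y_tr)
        top = order[:n_features_select]
        x_top, x_test = x_tr[:, top], x[i, top]
        col_mean = np.nanmean(x_top, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.5)
        x_top = np.where(np.isnan(x_top), col_mean, x_top)
        x_test = np.where(np.isnan(x_test), col_mean, x_test)
        # default penalty is L2
        model = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        model.fit(x_top, y_tr)
        scores[i] = model.predict_proba(x_test.reshape(1, -1))[0, 1]
        selected[str(samples[i])] = [str(feature_ids[j]) for j in top]

    score_series = pd.Series(scores, index=samples, name="tumor_score")
    roc, auc = roc_auc(score_series, matrix.labels)
    return ClassifierResult(score_series, matrix.labels, roc, auc, selected)


def roc_auc(scores: pd.Series, labels: pd.Series) -> tuple[pd.DataFrame, float]:
    """ROC by threshold sweep and AUC by the rank (Mann-Whitney) formulation.

    Ties contribute 1/2. With one class absent the AUC is undefined (NaN)
    and the ROC frame is empty.
    """
    y = (labels.loc[scores.index] == BC).astype(int).to_numpy()
    s = scores.to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        return pd.DataFrame(columns=["fpr", "tpr", "threshold"]), float("nan")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    rows = []
    for thr in thresholds:
        pred = s >= thr
        tpr = (pred & (y == 1)).sum() / n_pos
        fpr = (pred & (y == 0)).sum() / n_neg
        rows.append((fpr, tpr, thr))
    roc = pd.DataFrame(rows, columns=["fpr", "tpr", "threshold"])
    return roc, float(auc)
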