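"""Gene-level selection analysis of a barcode count matrix.

The model follows the four-step analysis popularised by MAGeCK for pooled
CRISPR screens, adapted here to barcoded transposon insertion data:

1. *Read-count normalisation* — median-of-ratios size factors (DESeq-style),
   or size factors computed over spiked-in wild-type control barcodes when a
   dilution series was included in the experiment.
2. *Mean–variance modelling* — a two-parameter overdispersion law
   sigma^2(mu) = mu + exp(b) * mu^k fitted across barcodes from the spread of
   normalised counts among control-condition replicates.
3. *Barcode ranking* — per barcode, one-sided negative-binomial tail
   p-values for the treatment mean against the control mean under the fitted
   variance law, plus a log2 fold change with pseudocount 1.
4. *Gene ranking* — alpha-robust-rank-aggregation (alpha-RRA): a gene's
   score is the smallest Beta order-statistic tail probability over its
   "good" member barcodes, calibrated by permuting barcode ranks over gene
   sizes; p-values are permutation-based and BH-adjusted per direction.

Wild-type control barcodes spiked at known relative concentrations also
drive a per-sample QC gate: an r^2 > 0.8 log-log dilution-series regression
is required for a sample to enter the analysis (minimum 4 control barcodes).

Use :class:`BarcodeScreenModel` (data in) and :class:`ScreenResults`
(estimates, diagnostics and ``summary()`` out).
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "qc_controls",
    "size_factors",
    "fit_mean_variance",
    "barcode_test",
    "rra_gene_rank",
    "MeanVarianceModel",
    "BarcodeScreenModel",
    "ScreenResults",
]

DEFAULT_ALPHA = 0.05
DEFAULT_N_PERM = 1000
PERM_ROUNDS_PER_GENE = 100
QC_R2_THRESHOLD = 0.8
MIN_CONTROL_BARCODES = 4

_WT_ALIASES = {"wt", "wildtype", "wild-type", "wild_type"}


def _wt_controls(controls: pd.DataFrame) -> pd.DataFrame:
    geno = controls["genotype"].astype(str).str.lower().str.strip()
    return controls[geno.isin(_WT_ALIASES)]


# ---------------------------------------------------------------------------
# step 0: control-barcode QC
# ---------------------------------------------------------------------------

def qc_controls(
    matrix: pd.DataFrame,
    controls: pd.DataFrame,
    r2_threshold: float = QC_R2_THRESHOLD,
) -> pd.DataFrame:
    """Dilution-series QC: per-sample regression of counts on concentration.

    For each sample, ordinary least squares of log10(count + 1) on
    log10(concentration) over the wild-type control barcodes; a sample is
    retained iff r^2 exceeds the threshold (default 0.8).  With fewer than 4
    wild-type control barcodes in the matrix the QC is skipped (all samples
    retained, ``applicable`` False).

    Returns a frame indexed by sample with columns r_squared, retained,
    applicable.
    """
    wt = _wt_controls(controls)
    wt = wt[wt["barcode"].isin(matrix.index)]
    samples = matrix.select_dtypes("number").columns
    if wt["barcode"].nunique() < MIN_CONTROL_BARCODES or wt["concentration"].nunique() < 2:
        warnings.warn(
            f"QC skipped: need >= {MIN_CONTROL_BARCODES} wild-type control barcodes "
            "spanning >= 2 concentrations; all samples retained"
        )
        return pd.DataFrame(
            {"r_squared": np.nan, "retained": True, "applicable": False},
            index=samples,
        )
    x = np.log10(wt["concentration"].to_numpy(dtype=float))
    rows = {}
    for sample in samples:
        y = np.log10(matrix.loc[wt["barcode"], sample].to_numpy(dtype=float) + 1.0)
        if np.std(y) == 0:
            r2 = 0.0
        else:
            r2 = float(sps.linregress(x, y).rvalue ** 2)
        rows[sample] = (r2, r2 > r2_threshold, True)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["r_squared", "retained", "applicable"]
    )


# ---------------------------------------------------------------------------
# step 1: normalisation
# ---------------------------------------------------------------------------

def size_factors(
    matrix: pd.DataFrame,
    method: str = "median",
    controls: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Median-of-ratios size factors, optionally over control barcodes only.

    The reference for barcode i is its geometric mean across samples
    (barcodes with any zero are excluded from the reference); the size factor
    of sample j is the median over barcodes of count_ij / reference_i.
    ``method="control"`` restricts both steps to the spiked-in control
    barcodes, which is the right choice when a bottleneck has distorted the
    bulk of the library.
    """
    counts = matrix.select_dtypes("number")
    if method == "control":
        if controls is None:
            raise ValueError("method='control' requires a control-barcode table")
        sel = counts.index.isin(controls["barcode"])
        if sel.sum() == 0:
            raise ValueError("no control barcodes found in the count matrix")
        counts = counts.loc[sel]
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no barcode has positive counts in every sample; "
            "median-of-ratios is undefined — consider control normalization"
        )
    log_ref = np.log(arr[positive]).mean(axis=1)
    ratios = np.log(arr[positive]) - log_ref[:, None]
    log_sf = np.median(ratios, axis=0)
    # fix the arbitrary overall scale: geometric mean 1 makes normalisation
    # idempotent (median-of-ratios of the normalised matrix returns 1)
    sf = np.exp(log_sf - log_sf.mean())
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# step 2: mean-variance modelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanVarianceModel:
    """Overdispersion law sigma^2(mu) = mu + exp(b) * mu^k.

    ``fallback_poisson`` marks cases where the law could not be fitted (too
    few overdispersed barcodes or a single replicate); the variance then
    degrades to the Poisson sigma^2 = mu.
    """

    k: float = float("nan")
    b: float = float("nan")
    fallback_poisson: bool = False
    n_barcodes_fit: int = 0

    def variance(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        if self.fallback_poisson:
            return mu.copy()
        with np.errstate(invalid="ignore"):
            extra = np.exp(self.b) * np.power(mu, self.k)
        return mu + np.where(mu > 0, extra, 0.0)


def fit_mean_variance(normalized_control: pd.DataFrame, min_barcodes: int = 10) -> MeanVarianceModel:
    """Fit the overdispersion law from control-condition replicates.

    Per barcode, the sample mean mu_i and variance v_i across replicates;
    over barcodes with v_i > mu_i > 0, least squares of log(v_i - mu_i) on
    log(mu_i) gives intercept b and slope k.  Falls back to Poisson when
    fewer than ``min_barcodes`` barcodes are overdispersed or only one
    replicate exists.
    """
    arr = normalized_control.select_dtypes("number").to_numpy(dtype=float)
    if arr.shape[1] < 2:
        return MeanVarianceModel(fallback_poisson=True)
    mu = arr.mean(axis=1)
    v = arr.var(axis=1, ddof=1)
    mask = (v > mu) & (mu > 0)
    if mask.sum() < min_barcodes:
        return MeanVarianceModel(fallback_poisson=True, n_barcodes_fit=int(mask.sum()))
    x = np.log(mu[mask])
    y = np.log(v[mask] - mu[mask])
    design = np.column_stack([np.ones_like(x), x])
    (b, k), *_ = np.linalg.lstsq(design, y, rcond=None)
    return MeanVarianceModel(k=float(k), b=float(b), n_barcodes_fit=int(mask.sum()))


# ---------------------------------------------------------------------------
# step 3: barcode ranking
# ---------------------------------------------------------------------------

def _nb_tail_pvalues(T: np.ndarray, mu: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided tail probabilities P(X <= T), P(X >= T) for X with the given
    mean/variance, negative binomial when overdispersed, Poisson otherwise.

    Non-integer observed means use the integer boundaries floor(T) for the
    lower tail and ceil(T) for the upper tail, which keeps
    p_neg + p_pos >= 1.
    """
    T = np.asarray(T, dtype=float)
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    lo = np.floor(T)
    hi = np.ceil(T)
    p_neg = np.empty_like(T)
    p_pos = np.empty_like(T)
    over = var > mu
    if over.any():
        m, v = mu[over], var[over]
        r = m**2 / (v - m)
        pp = r / (r + m)
        p_neg[over] = sps.nbinom.cdf(lo[over], r, pp)
        p_pos[over] = sps.nbinom.sf(hi[over] - 1, r, pp)
    if (~over).any():
        m = mu[~over]
        p_neg[~over] = sps.poisson.cdf(lo[~over], m)
        p_pos[~over] = sps.poisson.sf(hi[~over] - 1, m)
    eps = 1e-300
    return np.clip(p_neg, eps, 1.0), np.clip(p_pos, eps, 1.0)


def barcode_test(
    matrix: pd.DataFrame,
    design: pd.Series,
    sf: pd.Series,
    model: MeanVarianceModel,
    control_label: str = "control",
    treatment_label: str = "treatment",
    gene_map: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Rank barcodes by one-sided NB tail tests of treatment vs control.

    mu-hat is the mean normalised control count, T the mean normalised
    treatment count; the variance comes from the fitted law at mu-hat.
    Percentile ranks u = rank / N (ascending p, average ties) feed the gene
    aggregation.  Barcodes with zero mean in both conditions are excluded.
    """
    counts = matrix.select_dtypes("number")
    control_cols = design.index[design == control_label].tolist()
    treat_cols = design.index[design == treatment_label].tolist()
    norm = counts[control_cols + treat_cols] / sf[control_cols + treat_cols]
    mu = norm[control_cols].mean(axis=1).to_numpy()
    T = norm[treat_cols].mean(axis=1).to_numpy()
    keep = (mu > 0) | (T > 0)
    barcodes = counts.index[keep]
    mu, T = mu[keep], T[keep]
    var = model.variance(mu)
    p_neg, p_pos = _nb_tail_pvalues(T, mu, var)
    lfc = np.log2((T + 1.0) / (mu + 1.0))
    n = len(barcodes)
    out = pd.DataFrame(
        {
            "barcode": barcodes,
            "control_mean": mu,
            "treatment_mean": T,
            "lfc": lfc,
            "p_neg": p_neg,
            "p_pos": p_pos,
            "rank_neg": sps.rankdata(p_neg) / n,
            "rank_pos": sps.rankdata(p_pos) / n,
        }
    )
    if gene_map is not None:
        out["gene"] = out["barcode"].map(gene_map).fillna("")
    else:
        out["gene"] = ""
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# step 4: gene ranking (alpha-RRA)
# ---------------------------------------------------------------------------

def _rra_rho(u_sorted: np.ndarray, good_sorted: np.ndarray) -> float:
    """alpha-RRA score for one gene: min over good order statistics of the
    Beta(k, m-k+1) lower tail at u_(k); 1 when no member is good."""
    m = len(u_sorted)
    best = 1.0
    for k in range(1, m + 1):
        if good_sorted[k - 1]:
            best = min(best, float(sps.beta.cdf(u_sorted[k - 1], k, m - k + 1)))
    return best


def _sample_without_replacement(rng, n: int, m: int, rows: int) -> np.ndarray:
    """rows x m index matrix, each row m distinct draws from range(n)."""
    idx = rng.integers(0, n, size=(rows, m))
    while True:
        dup = (np.sort(idx, axis=1)[:, 1:] == np.sort(idx, axis=1)[:, :-1]).any(axis=1)
        if not dup.any():
            return idx
        idx[dup] = rng.integers(0, n, size=(int(dup.sum()), m))


def _rra_null(u: np.ndarray, good: np.ndarray, sizes: Sequence[int], n_perm: int, rng) -> dict[int, np.ndarray]:
    """Permutation null of rho per gene size: barcode ranks are randomly
    reassigned to genes of each size, n_perm times (vectorised)."""
    null: dict[int, np.ndarray] = {}
    n = len(u)
    for m in sorted(set(sizes)):
        idx = _sample_without_replacement(rng, n, m, n_perm)
        u_mat = u[idx]
        good_mat = good[idx]
        order = np.argsort(u_mat, axis=1)
        u_sorted = np.take_along_axis(u_mat, order, axis=1)
        good_sorted = np.take_along_axis(good_mat, order, axis=1)
        scores = np.full((n_perm, m), np.inf)
        for k in range(1, m + 1):
            col = sps.beta.cdf(u_sorted[:, k - 1], k, m - k + 1)
            scores[:, k - 1] = np.where(good_sorted[:, k - 1], col, np.inf)
        rho = scores.min(axis=1)
        rho[np.isinf(rho)] = 1.0
        null[m] = np.sort(rho)
    return null


def rra_gene_rank(
    barcode_stats: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Aggregate barcode ranks into gene-level selection scores (alpha-RRA).

    Per gene and direction, only members with direction p-value below alpha
    ("good" barcodes) enter the minimum over Beta order-statistic tails;
    permutation of barcode ranks over gene sizes calibrates the score into a
    p-value with +1 smoothing, BH-adjusted per direction.  The gene LFC is
    the median of member LFCs.

    ``n_perm=None`` (the default) scales the permutation count with the
    number of genes (PERM_ROUNDS_PER_GENE x genes, at least 1000): the
    smallest achievable p-value is 1/(n_perm+1), so the permutation count
    must grow with the multiple-testing burden for BH-adjusted discoveries
    to be resolvable at conventional FDR levels.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    stats_df = barcode_stats[barcode_stats["gene"] != ""]
    genes = stats_df.groupby("gene", sort=True)
    sizes = genes.size()
    if n_perm is None:
        n_perm = max(DEFAULT_N_PERM, PERM_ROUNDS_PER_GENE * len(sizes))
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives unstable permutation p-values")
    out_rows = []
    per_dir: dict[str, dict[str, np.ndarray]] = {}
    for direction, p_col, u_col in (("neg", "p_neg", "rank_neg"), ("pos", "p_pos", "rank_pos")):
        u_all = stats_df[u_col].to_numpy()
        good_all = stats_df[p_col].to_numpy() < alpha
        null = _rra_null(u_all, good_all, sizes.tolist(), n_perm, rng)
        rho_obs = {}
        p_obs = {}
        for gene, grp in genes:
            u = grp[u_col].to_numpy()
            good = grp[p_col].to_numpy() < alpha
            order = np.argsort(u)
            rho = _rra_rho(u[order], good[order])
            m = len(u)
            n_le = int(np.searchsorted(null[m], rho, side="right"))
            rho_obs[gene] = rho
            p_obs[gene] = (1.0 + n_le) / (1.0 + n_perm)
        per_dir[direction] = {"rho": rho_obs, "p": p_obs}
    gene_names = list(sizes.index)
    lfc = genes["lfc"].median()
    p_neg = np.array([per_dir["neg"]["p"][g] for g in gene_names])
    p_pos = np.array([per_dir["pos"]["p"][g] for g in gene_names])
    fdr_neg = multipletests(p_neg, method="fdr_bh")[1]
    fdr_pos = multipletests(p_pos, method="fdr_bh")[1]
    for i, g in enumerate(gene_names):
        out_rows.append(
            (
                g,
                int(sizes[g]),
                float(lfc[g]),
                per_dir["neg"]["rho"][g],
                p_neg[i],
                fdr_neg[i],
                per_dir["pos"]["rho"][g],
                p_pos[i],
                fdr_pos[i],
            )
        )
    return pd.DataFrame(
        out_rows,
        columns=[
            "gene",
            "num_barcodes",
            "LFC",
            "rho_neg",
            "neg_selection_pval",
            "neg_selection_fdr",
            "rho_pos",
            "pos_selection_pval",
            "pos_selection_fdr",
        ],
    )


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class BarcodeScreenModel:
    """Two-condition selection screen on a barcode count matrix.

    Parameters
    ----------
    matrix : DataFrame
        Barcodes (index) × samples (columns) raw counts; an optional
        non-numeric annotation column maps barcodes to genes.
    design : Series or dict
        sample_id -> condition label.
    control, treatment : str
        The two condition labels to compare.
    controls : DataFrame, optional
        Spiked-in control barcodes (columns barcode, genotype,
        concentration); enables QC gating and control normalisation.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        design,
        control: str = "control",
        treatment: str = "treatment",
        controls: Optional[pd.DataFrame] = None,
        gene_column: Optional[str] = None,
        alpha: float = DEFAULT_ALPHA,
        n_perm: Optional[int] = None,
    ):
        self.matrix = matrix
        self.design = pd.Series(design)
        self.control = control
        self.treatment = treatment
        self.controls = controls
        self.alpha = alpha
        self.n_perm = n_perm
        counts = matrix.select_dtypes("number")
        missing = [s for s in self.design.index if s not in counts.columns]
        if missing:
            raise ValueError(f"design samples not in count matrix: {missing}")
        for label in (control, treatment):
            if (self.design == label).sum() < 1:
                raise ValueError(f"no samples with condition {label!r}")
        if gene_column is None:
            nonnum = [c for c in matrix.columns if c not in counts.columns]
            gene_column = nonnum[0] if nonnum else None
        self.gene_column = gene_column

    @classmethod
    def from_csv(
        cls,
        counts_csv: str,
        design_csv: str,
        controls_csv: Optional[str] = None,
        **kwargs,
    ) -> "BarcodeScreenModel":
        matrix = pd.read_csv(counts_csv, index_col=0, keep_default_na=False)
        for col in matrix.columns:
            try:
                matrix[col] = pd.to_numeric(matrix[col])
            except (ValueError, TypeError):
                pass
        design_df = pd.read_csv(design_csv)
        design = pd.Series(
            design_df.iloc[:, 1].values, index=design_df.iloc[:, 0].astype(str)
        )
        controls = pd.read_csv(controls_csv) if controls_csv else None
        return cls(matrix, design, controls=controls, **kwargs)

    def fit(self, seed: Optional[int] = None) -> "ScreenResults":
        """Run QC, normalisation, mean-variance fit, barcode test and RRA."""
        rng = np.random.default_rng(seed)
        design = self.design[self.design.isin([self.control, self.treatment])]
        matrix = self.matrix
        counts = matrix.select_dtypes("number")

        qc = None
        if self.controls is not None:
            qc = qc_controls(counts[design.index], self.controls)
            failed = qc.index[~qc["retained"]].tolist()
            if failed:
                logger.info("samples removed by dilution-series QC: %s", failed)
            design = design.drop(index=failed, errors="ignore")
            treat_left = (design == self.treatment).sum()
            ctrl_left = (design == self.control).sum()
            if treat_left == 0 or ctrl_left == 0:
                raise RuntimeError(
                    "all samples of one condition failed dilution-series QC "
                    f"(removed: {failed}); cannot analyze"
                )

        method = "control" if self.controls is not None else "median"
        sf = size_factors(counts[design.index], method=method, controls=self.controls)

        control_cols = design.index[design == self.control].tolist()
        norm_control = counts[control_cols] / sf[control_cols]
        mv = fit_mean_variance(norm_control)

        gene_map = None
        if self.gene_column is not None:
            ann = matrix[self.gene_column].astype(str)
            gene_map = ann[ann != ""]
        bstats = barcode_test(
            matrix,
            design,
            sf,
            mv,
            control_label=self.control,
            treatment_label=self.treatment,
            gene_map=gene_map,
        )
        gstats = rra_gene_rank(bstats, alpha=self.alpha, n_perm=self.n_perm, rng=rng)
        return ScreenResults(
            model=self,
            gene_results=gstats,
            barcode_results=bstats,
            qc=qc,
            size_factors=sf,
            mean_variance=mv,
            seed=seed,
        )


@dataclass
class ScreenResults:
    """Fitted screen: gene and barcode tables, diagnostics, summary."""

    model: BarcodeScreenModel
    gene_results: pd.DataFrame
    barcode_results: pd.DataFrame
    qc: Optional[pd.DataFrame]
    size_factors: pd.Series
    mean_variance: MeanVarianceModel
    seed: Optional[int] = None

    def hits(
        self,
        fdr_threshold: float = 0.05,
        lfc_threshold: float = -0.6,
        direction: str = "neg",
    ) -> pd.DataFrame:
        """Genes with a significant fitness change.

        Default thresholds (FDR < 0.05 and LFC < -0.6) select depleted hits,
        i.e. fitness factors; ``direction="pos"`` with a positive threshold
        selects enriched genes.
        """
        g = self.gene_results
        if direction == "neg":
            sel = (g["neg_selection_fdr"] < fdr_threshold) & (g["LFC"] < lfc_threshold)
        else:
            sel = (g["pos_selection_fdr"] < fdr_threshold) & (g["LFC"] > abs(lfc_threshold))
        return g[sel].reset_index(drop=True)

    def summary(self) -> str:
        mv = self.mean_variance
        lines = [
            "Barcode screen selection analysis (alpha-RRA)",
            "=" * 46,
            f"samples analyzed:     {len(self.size_factors)}"
            f"  ({self.model.control} vs {self.model.treatment})",
            f"barcodes tested:      {len(self.barcode_results)}",
            f"genes ranked:         {len(self.gene_results)}",
            f"normalization:        {'control' if self.model.controls is not None else 'median'}-of-ratios",
            (
                "mean-variance model:  Poisson fallback"
                if mv.fallback_poisson
                else f"mean-variance model:  sigma^2 = mu + {np.exp(mv.b):.4g} * mu^{mv.k:.3f}"
                     f"  ({mv.n_barcodes_fit} barcodes)"
            ),
        ]
        if self.qc is not None and self.qc["applicable"].any():
            for sample, row in self.qc.iterrows():
                flag = "retained" if row["retained"] else "REMOVED"
                lines.append(f"QC {sample}: r^2 = {row['r_squared']:.3f} ({flag})")
        n_neg = int((self.gene_results["neg_selection_fdr"] < 0.05).sum())
        n_pos = int((self.gene_results["pos_selection_fdr"] < 0.05).sum())
        lines += [
            f"genes FDR<0.05 (neg): {n_neg}",
            f"genes FDR<0.05 (pos): {n_pos}",
        ]
        return "\n".join(lines)

    def write(self, output_dir: str, name: str = "screen") -> dict[str, str]:
        os.makedirs(output_dir, exist_ok=True)
        paths = {
            "gene": os.path.join(output_dir, f"{name}_rra_results.csv"),
            "barcode": os.path.join(output_dir, f"{name}_barcode_stats.csv"),
        }
        cols = [
            "gene", "num_barcodes", "LFC",
            "neg_selection_pval", "neg_selection_fdr",
            "pos_selection_pval", "pos_selection_fdr",
        ]
        self.gene_results[cols].to_csv(paths["gene"], index=False, lineterminator="\n")
        self.barcode_results.to_csv(paths["barcode"], index=False, lineterminator="\n")
        if self.qc is not None:
            paths["qc"] = os.path.join(output_dir, f"{name}_qc.txt")
            with open(paths["qc"], "w") as fh:
                fh.write(self.qc.to_string() + "\n")
        return paths
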