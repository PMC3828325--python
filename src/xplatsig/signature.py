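"""Pathway-activation signatures: training, prediction, cross-validation.

A signature is a quantitative model that predicts the probability that a
pathway is active in a sample from the expression of a selected gene set.
Training follows the classic metagene/probit pipeline:

1. quantile-normalize the training matrix (columns forced to a common
   reference distribution, the mean of the sorted columns);
2. rank genes by the Pearson correlation of their expression with the
   binary phenotype and keep the top ``n_genes`` by ``|r|``;
3. standardize the selected genes (row center/scale) and compress them
   into ``k`` *metagenes* — the first k left singular vectors of the
   standardized gene × sample matrix; sample scores are the projections
   onto that basis;
4. fit a probit regression of the phenotype on the metagene scores.
   The default fitter is the Albert–Chib latent-variable Gibbs sampler
   with independent N(0, τ²=100) priors, which keeps coefficients finite
   even under complete separation (common with clean training cohorts);
   a ridge-penalized maximum-likelihood fitter matching the same prior
   is available as a fast path.

Prediction quantile-normalizes new samples to the *stored* training
reference, applies the stored centering/scaling, projects onto the
metagene basis and maps through the standard normal CDF.  A signature
trained on one platform is applied to another by translating its probe
ids through the mutual-best-match pairs of a
:class:`~xplatsig.probes.MappingTable`.

The public surface follows the model/results idiom: construct
:class:`PathwaySignatureModel` from a matrix and labels, call
:meth:`~PathwaySignatureModel.fit` to obtain a
:class:`SignatureResults`, then ``predict`` / ``summary`` /
``to_json`` on the results object.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import log_ndtr, ndtr, ndtri

from . import io as xio

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureParams",
    "PathwaySignatureModel",
    "SignatureResults",
    "quantile_normalize",
    "select_signature_genes",
    "compute_metagenes",
    "fit_probit_gibbs",
    "fit_probit_penalized_mle",
    "create_signature",
    "loocv_predict",
    "signature_overlap",
]

_PROB_EPS = 1e-12  # keep predicted probabilities strictly inside (0, 1)


@dataclass(frozen=True)
class SignatureParams:
    """Hyperparameters of the signature pipeline.

    ``n_genes`` and ``n_metagenes`` follow the published pathway settings
    (150 genes / 2 metagenes for E2F1-type signatures; up to 500 genes and
    3 metagenes for broader programs).  ``tau2`` is the prior variance of
    the probit coefficients; ``sampler`` chooses between the Gibbs
    sampler (posterior-mean coefficients) and the ridge-penalized MLE.
    """

    n_genes: int = 150
    n_metagenes: int = 2
    normalization: str = "quantile"
    seed: int = 0
    sampler: str = "gibbs"
    n_iterations: int = 2000
    n_burnin: int = 500
    tau2: float = 100.0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_metagenes < 1:
            raise ValueError("n_genes and n_metagenes must be positive")
        if self.n_metagenes > self.n_genes:
            raise ValueError("n_metagenes cannot exceed n_genes")
        if self.normalization not in {"quantile", "none"}:
            raise ValueError("normalization must be 'quantile' or 'none'")
        if self.sampler not in {"gibbs", "penalized_mle"}:
            raise ValueError("sampler must be 'gibbs' or 'penalized_mle'")
        if self.n_iterations < 1 or self.n_burnin < 0:
            raise ValueError("invalid sampler iteration counts")


# ---------------------------------------------------------------------------
# pipeline stages


def quantile_normalize(matrix: pd.DataFrame,
                       reference: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Force every column's value distribution onto a common reference.

    With ``reference=None`` the reference is the mean of the sorted
    columns of ``matrix`` itself.  Within-column ranks are preserved and
    ties receive the average of the reference values they span.
    """
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    if reference is None:
        reference = np.sort(values, axis=0).mean(axis=1)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (n,):
            raise ValueError(
                f"reference length {reference.shape} does not match "
                f"row count {n}"
            )
        if np.any(np.diff(reference) < 0):
            reference = np.sort(reference)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")  # 1..n
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _pointwise_label_correlation(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every row of ``values`` against the 0/1 label vector."""
    yc = y - y.mean()
    vc = values - values.mean(axis=1, keepdims=True)
    num = vc @ yc
    den = np.sqrt((vc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


def select_signature_genes(train: pd.DataFrame, labels: pd.Series,
                           n_genes: int) -> pd.DataFrame:
    """Top ``n_genes`` probes by |Pearson r| against the binary phenotype.

    Returns a frame with columns ``probe_id`` and ``r`` ordered by
    descending |r|, ties broken by probe id.  Zero-variance probes rank
    last.  Both classes must be present.
    """
    labels = xio.check_labels_against_matrix(labels, train)
    if n_genes > train.shape[0]:
        raise ValueError(f"n_genes={n_genes} exceeds probe count {train.shape[0]}")
    y = labels.loc[train.columns.intersection(labels.index)]
    sub = train[y.index]
    r = _pointwise_label_correlation(sub.to_numpy(dtype=float),
                                     y.to_numpy(dtype=float))
    frame = pd.DataFrame({"probe_id": train.index.astype(str), "r": r})
    frame["abs_r"] = frame["r"].abs().fillna(-1.0)
    frame = frame.sort_values(["abs_r", "probe_id"], ascending=[False, True],
                              kind="stable").head(n_genes)
    return frame.drop(columns="abs_r").reset_index(drop=True)


def compute_metagenes(train_selected: pd.DataFrame, k: int):
    """Metagene basis of a selected-gene training matrix.

    Rows are centered and scaled to unit variance (ddof=1; constant rows
    keep scale 1), then the basis is the first ``k`` left singular
    vectors of the standardized genes × samples matrix.  The sign of each
    basis vector is fixed so its largest-magnitude loading is positive.

    Returns ``(basis, means, scales, scores)`` where ``basis`` is genes×k
    with orthonormal columns and ``scores`` is k×samples.
    """
    values = train_selected.to_numpy(dtype=float)
    g, n = values.shape
    if k > min(g, n):
        raise ValueError(f"k={k} exceeds matrix dimensions {g}x{n}")
    means = values.mean(axis=1)
    scales = values.std(axis=1, ddof=1) if n > 1 else np.ones(g)
    scales = np.where(scales > 0, scales, 1.0)
    z = (values - means[:, None]) / scales[:, None]
    u, s, _vt = linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * max(g, n) * np.finfo(float).eps).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the "
                         "standardized training matrix")
    basis = u[:, :k].copy()
    for j in range(k):
        if basis[np.argmax(np.abs(basis[:, j])), j] < 0:
            basis[:, j] = -basis[:, j]
    scores = basis.T @ z
    return basis, means, scales, scores


def _neg_log_posterior(beta, X, y, tau2):
    eta = X @ beta
    ll = y @ log_ndtr(eta) + (1 - y) @ log_ndtr(-eta)
    return -ll + 0.5 * (beta @ beta) / tau2


def _neg_log_posterior_grad(beta, X, y, tau2):
    eta = X @ beta
    log_pdf = -0.5 * eta**2 - 0.5 * np.log(2 * np.pi)
    w = y * np.exp(log_pdf - log_ndtr(eta)) \
        - (1 - y) * np.exp(log_pdf - log_ndtr(-eta))
    return -(X.T @ w) + beta / tau2


def fit_probit_penalized_mle(scores: np.ndarray, y: np.ndarray,
                             tau2: float = 100.0, tol: float = 1e-8):
    """Ridge-penalized probit MLE (the MAP under the N(0, τ²I) prior).

    ``scores`` is samples × k (no intercept column); an intercept is
    prepended internally.  Returns the coefficient vector
    ``[intercept, w_1..w_k]``.
    """
    X = np.column_stack([np.ones(len(y)), np.asarray(scores, dtype=float)])
    y = np.asarray(y, dtype=float)
    res = optimize.minimize(
        _neg_log_posterior, np.zeros(X.shape[1]),
        args=(X, y, tau2), jac=_neg_log_posterior_grad,
        method="L-BFGS-B", options={"gtol": tol, "ftol": 1e-14, "maxiter": 500},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-4:
        raise RuntimeError(f"probit MAP optimization failed: {res.message}")
    return res.x


def _sample_truncated_normal(mu: np.ndarray, positive: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw z ~ N(mu, 1) truncated to z>0 where positive else z<0.

    Inverse-CDF sampling in the (numerically safe) direction of the
    truncation tail.
    """
    u = rng.random(mu.shape)
    z = np.empty_like(mu)
    pos = positive
    # z > 0: z = mu + ndtri(F(-mu) + u (1 - F(-mu))) via survival mixing
    tail = ndtr(-mu[pos])
    z[pos] = mu[pos] + ndtri(np.clip(tail + u[pos] * (1.0 - tail),
                                     _PROB_EPS, 1 - _PROB_EPS))
    neg = ~pos
    tail = ndtr(mu[neg])  # P(z < 0) given mean mu
    z[neg] = mu[neg] + ndtri(np.clip(u[neg] * (1.0 - tail),
                                     _PROB_EPS, 1 - _PROB_EPS))
    return z


def fit_probit_gibbs(scores: np.ndarray, y: np.ndarray, *,
                     tau2: float = 100.0, n_iterations: int = 2000,
                     n_burnin: int = 500,
                     rng: Optional[np.random.Generator] = None):
    """Albert–Chib latent-variable Gibbs sampler for Bayesian probit.

    Data augmentation: latent z_i ~ N(x_i'β, 1), observed y_i = 1{z_i>0}.
    Conditionals are a truncated normal for z and a multivariate normal
    for β under the N(0, τ²I) prior.  Returns ``(posterior_mean,
    posterior_sd)`` over ``n_iterations`` retained draws after
    ``n_burnin``; coefficients are ``[intercept, w_1..w_k]``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(len(y)), np.asarray(scores, dtype=float)])
    y = np.asarray(y)
    positive = y.astype(bool)
    p = X.shape[1]
    precision = X.T @ X + np.eye(p) / tau2
    chol = linalg.cholesky(precision, lower=True)
    beta = np.zeros(p)
    draws = np.empty((n_iterations, p))
    for it in range(n_burnin + n_iterations):
        mu = X @ beta
        z = _sample_truncated_normal(mu, positive, rng)
        mean = linalg.cho_solve((chol, True), X.T @ z)
        beta = mean + linalg.solve_triangular(chol.T, rng.standard_normal(p),
                                              lower=False)
        if it >= n_burnin:
            draws[it - n_burnin] = beta
    return draws.mean(axis=0), draws.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# model / results


class PathwaySignatureModel:
    """Pathway signature trainer (model object).

    Parameters
    ----------
    endog : pandas.Series
        Binary phenotype per training sample (0 = control, 1 = pathway
        on); index must be sample ids present in ``exog``.
    exog : pandas.DataFrame
        Probes × samples log2 expression matrix for the training cohort.
    params : SignatureParams
        Pipeline hyperparameters.
    platform_id : str
        Identifier of the platform the training matrix was measured on;
        used when translating the signature across platforms.
    """

    def __init__(self, endog: pd.Series, exog: pd.DataFrame,
                 params: SignatureParams = SignatureParams(),
                 platform_id: str = "A"):
        xio.validate_expression(exog)
        endog = xio.check_labels_against_matrix(endog, exog)
        if params.n_metagenes > len(endog):
            raise ValueError("n_metagenes cannot exceed the number of "
                             "training samples")
        self.endog = endog.astype(int)
        self.exog = exog
        self.params = params
        self.platform_id = platform_id

    @classmethod
    def from_files(cls, expr_path, labels_path,
                   params: SignatureParams = SignatureParams(),
                   format: str = "tsv", platform_id: str = "A"):
        expr = xio.read_expression(expr_path, format=format)
        labels = xio.read_labels(labels_path)
        return cls(labels, expr, params=params, platform_id=platform_id)

    def fit(self, rng: Optional[np.random.Generator] = None) -> "SignatureResults":
        params = self.params
        if rng is None:
            rng = np.random.default_rng(params.seed)
        train = self.exog[self.endog.index]
        if params.normalization == "quantile":
            reference = np.sort(train.to_numpy(dtype=float), axis=0).mean(axis=1)
            train = quantile_normalize(train, reference)
        else:
            reference = None
        selected = select_signature_genes(train, self.endog, params.n_genes)
        sub = train.loc[selected["probe_id"]]
        basis, means, scales, scores = compute_metagenes(sub, params.n_metagenes)
        y = self.endog.to_numpy()
        if params.sampler == "gibbs":
            coef, coef_sd = fit_probit_gibbs(
                scores.T, y, tau2=params.tau2,
                n_iterations=params.n_iterations, n_burnin=params.n_burnin,
                rng=rng)
        else:
            coef = fit_probit_penalized_mle(scores.T, y, tau2=params.tau2)
            coef_sd = np.full_like(coef, np.nan)
        return SignatureResults(
            model=self, selected_genes=selected,
            quantile_reference=reference, gene_means=means,
            gene_scales=scales, metagene_basis=basis,
            probit_coefficients=coef, probit_coefficient_sd=coef_sd,
            training_scores=scores, params=params,
            platform_id=self.platform_id,
        )


@dataclass
class SignatureResults:
    """A fitted pathway signature.

    Carries everything prediction needs: the ordered selected genes with
    their phenotype correlations, the quantile reference distribution,
    per-gene centering/scaling constants, the metagene basis, and the
    probit coefficients (posterior mean and SD under the Gibbs sampler).
    """

    selected_genes: pd.DataFrame
    quantile_reference: Optional[np.ndarray]
    gene_means: np.ndarray
    gene_scales: np.ndarray
    metagene_basis: np.ndarray
    probit_coefficients: np.ndarray
    probit_coefficient_sd: np.ndarray
    params: SignatureParams
    platform_id: str = "A"
    training_scores: Optional[np.ndarray] = None
    model: Optional[PathwaySignatureModel] = field(default=None, repr=False)

    #: maximum tolerated fraction of signature genes absent at prediction
    missing_gene_tolerance: float = 0.05

    # -- prediction ------------------------------------------------------

    def _resolve_genes(self, test: pd.DataFrame, mapping=None):
        """Map signature probe ids into the test matrix's row space.

        With ``mapping`` given, ids are translated through its mutual
        pairs (in the direction matching this signature's platform).
        Returns (test row ids, positional indices into the signature's
        gene arrays) for the genes that could be resolved.
        """
        wanted = self.selected_genes["probe_id"].tolist()
        if mapping is not None:
            if self.platform_id == mapping.platform_a_id:
                table = mapping.translation()
            elif self.platform_id == mapping.platform_b_id:
                table = mapping.translation(reverse=True)
            else:
                raise ValueError(
                    f"mapping covers platforms {mapping.platform_a_id!r}/"
                    f"{mapping.platform_b_id!r}, not {self.platform_id!r}"
                )
            translated = [table.get(g) for g in wanted]
        else:
            translated = wanted
        rows, kept_idx, missing = [], [], []
        test_rows = set(test.index)
        for i, (orig, trans) in enumerate(zip(wanted, translated)):
            if trans is not None and trans in test_rows:
                rows.append(trans)
                kept_idx.append(i)
            else:
                missing.append(orig)
        frac = len(missing) / len(wanted)
        if frac > self.missing_gene_tolerance:
            raise ValueError(
                f"{len(missing)}/{len(wanted)} signature genes missing from "
                f"the test matrix (> {self.missing_gene_tolerance:.0%}): "
                f"{', '.join(missing[:10])}"
            )
        if missing:
            logger.warning("prediction proceeding without %d/%d signature "
                           "gene(s)", len(missing), len(wanted))
        return rows, np.asarray(kept_idx, dtype=int), missing

    def predict(self, test: pd.DataFrame, mapping=None) -> pd.DataFrame:
        """Pathway-activation probability per test sample.

        Columns of ``test`` are quantile-normalized to the stored
        training reference, the signature genes are standardized with the
        stored constants, projected onto the metagene basis, and the
        linear predictor is mapped through Φ.  Up to 5% of signature
        genes may be missing (dropped with a warning); more is an error.
        """
        xio.validate_expression(test)
        if self.quantile_reference is not None:
            if len(self.quantile_reference) == test.shape[0]:
                reference = self.quantile_reference
            else:
                # rank space differs; interpolate the stored reference
                reference = np.interp(
                    np.linspace(0, 1, test.shape[0]),
                    np.linspace(0, 1, len(self.quantile_reference)),
                    self.quantile_reference)
            test = quantile_normalize(test, reference)
        rows, idx, _missing = self._resolve_genes(test, mapping)
        sub = test.loc[rows].to_numpy(dtype=float)
        z = (sub - self.gene_means[idx][:, None]) / self.gene_scales[idx][:, None]
        scores = self.metagene_basis[idx].T @ z  # k × samples
        coef = self.probit_coefficients
        eta = coef[0] + coef[1:] @ scores
        prob = np.clip(ndtr(eta), _PROB_EPS, 1 - _PROB_EPS)
        return pd.DataFrame({"probability": prob, "linear_predictor": eta},
                            index=pd.Index(test.columns, name="sample_id"))

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        coef = self.probit_coefficients
        sd = self.probit_coefficient_sd
        names = ["intercept"] + [f"metagene_{j+1}"
                                 for j in range(len(coef) - 1)]
        lines = [
            "Pathway signature (metagene probit)",
            f"  platform            {self.platform_id}",
            f"  genes selected      {len(self.selected_genes)}",
            f"  metagenes           {self.params.n_metagenes}",
            f"  sampler             {self.params.sampler}",
            f"  normalization       {self.params.normalization}",
            "",
            f"  {'coefficient':<14}{'estimate':>12}{'posterior sd':>14}",
        ]
        for name, c, s in zip(names, coef, sd):
            s_txt = f"{s:>14.4f}" if np.isfinite(s) else f"{'--':>14}"
            lines.append(f"  {name:<14}{c:>12.4f}{s_txt}")
        top = self.selected_genes.head(5)
        lines.append("")
        lines.append("  top genes by |r|: "
                     + ", ".join(f"{p} (r={r:+.3f})"
                                 for p, r in zip(top["probe_id"], top["r"])))
        return "\n".join(lines)

    # -- (de)serialization ----------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "format": "xplatsig-signature-1",
            "platform_id": self.platform_id,
            "params": asdict(self.params),
            "selected_genes": self.selected_genes["probe_id"].tolist(),
            "gene_r": [float(v) for v in self.selected_genes["r"]],
            "quantile_reference": (None if self.quantile_reference is None
                                   else self.quantile_reference.tolist()),
            "gene_means": self.gene_means.tolist(),
            "gene_scales": self.gene_scales.tolist(),
            "metagene_basis": self.metagene_basis.tolist(),
            "probit_coefficients": self.probit_coefficients.tolist(),
            "probit_coefficient_sd": [
                None if not np.isfinite(v) else float(v)
                for v in self.probit_coefficient_sd
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SignatureResults":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        if doc.get("format") != "xplatsig-signature-1":
            raise ValueError("not a serialized signature document")
        selected = pd.DataFrame({"probe_id": doc["selected_genes"],
                                 "r": doc["gene_r"]})
        ref = doc["quantile_reference"]
        sd = [np.nan if v is None else v for v in doc["probit_coefficient_sd"]]
        return cls(
            selected_genes=selected,
            quantile_reference=None if ref is None else np.asarray(ref),
            gene_means=np.asarray(doc["gene_means"]),
            gene_scales=np.asarray(doc["gene_scales"]),
            metagene_basis=np.asarray(doc["metagene_basis"]),
            probit_coefficients=np.asarray(doc["probit_coefficients"]),
            probit_coefficient_sd=np.asarray(sd),
            params=SignatureParams(**doc["params"]),
            platform_id=doc["platform_id"],
        )


# ---------------------------------------------------------------------------
# convenience functions


def create_signature(train: pd.DataFrame, labels: pd.Series,
                     params: SignatureParams = SignatureParams(),
                     platform_id: str = "A") -> SignatureResults:
    """Train a signature: shorthand for ``PathwaySignatureModel(...).fit()``."""
    return PathwaySignatureModel(labels, train, params=params,
                                 platform_id=platform_id).fit()


def loocv_predict(train: pd.DataFrame, labels: pd.Series,
                  params: SignatureParams = SignatureParams(),
                  platform_id: str = "A") -> pd.DataFrame:
    """Leave-one-out cross-validated pathway probabilities.

    The *entire* pipeline — normalization reference, gene selection,
    metagenes, probit — is refit on each fold's n−1 samples before the
    held-out sample is scored, so the probabilities are free of
    selection bias.  Requires ≥3 samples per class and both classes in
    every fold.
    """
    labels = xio.check_labels_against_matrix(labels, train)
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError("LOOCV needs >= 3 samples per class")
    rows = []
    for fold, sample in enumerate(labels.index):
        keep = labels.index.drop(sample)
        fold_labels = labels.loc[keep]
        if fold_labels.nunique() < 2:
            raise ValueError(f"fold holding out {sample!r} loses a class")
        fold_rng = np.random.default_rng([params.seed, fold])
        model = PathwaySignatureModel(fold_labels, train[keep], params=params,
                                      platform_id=platform_id)
        result = model.fit(rng=fold_rng)
        pred = result.predict(train[[sample]])
        rows.append((sample, int(labels.loc[sample]),
                     float(pred["probability"].iloc[0]),
                     float(pred["linear_predictor"].iloc[0])))
    return pd.DataFrame(rows, columns=["sample_id", "label", "probability",
                                       "linear_predictor"]).set_index("sample_id")


def cross_platform_predict(result: SignatureResults, mapping,
                           test_other_platform: pd.DataFrame) -> pd.DataFrame:
    """Apply a signature to another platform's matrix via a probe mapping.

    Shorthand for ``result.predict(test, mapping=mapping)``: the
    signature's probe ids are translated through the mapping's mutual
    pairs before scoring.
    """
    return result.predict(test_other_platform, mapping=mapping)


def signature_overlap(result_a: SignatureResults, result_b: SignatureResults,
                      mapping) -> dict:
    """Gene-set overlap of two signatures trained on mapped platforms.

    A gene counts as *common* when the mutual-best-match partner of a
    platform-A selected probe appears in the platform-B selected list.
    Percent overlap is common / n_genes × 100.
    """
    if len(result_a.selected_genes) != len(result_b.selected_genes):
        raise ValueError("signatures must be trained with the same n_genes")
    if {result_a.platform_id, result_b.platform_id} != {mapping.platform_a_id,
                                                        mapping.platform_b_id}:
        raise ValueError(
            f"mapping covers {mapping.platform_a_id!r}/{mapping.platform_b_id!r}; "
            f"signatures are on {result_a.platform_id!r}/{result_b.platform_id!r}"
        )
    if result_a.platform_id == mapping.platform_a_id:
        table = mapping.translation()
    else:
        table = mapping.translation(reverse=True)
    genes_a = result_a.selected_genes["probe_id"].tolist()
    genes_b = set(result_b.selected_genes["probe_id"])
    common = [g for g in genes_a if table.get(g) in genes_b]
    n = len(genes_a)
    return {
        "n_genes": n,
        "common": len(common),
        "unique_a": n - len(common),
        "unique_b": n - len(common),
        "percent_overlap": 100.0 * len(common) / n,
        "common_genes_a": common,
    }
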