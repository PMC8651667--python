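"""Batch correction for count matrices in the ComBat-seq style.

Per gene and batch, counts are modelled as negative binomial with the
biological condition as covariate (log link, batch-specific intercept); each
observed count is then quantile-mapped from its fitted batch distribution to a
batch-free target distribution — the sample-count-weighted pool of the batch
fits — preserving the integer nature of the counts. Numerical parity with the
reference ComBat-seq implementation (empirical-Bayes shrinkage of batch
parameters) is deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._nbinom import nb_cdf, nb_ppf, fit_alpha_ml
from .io import CountMatrix, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

MEAN_FLOOR = 0.05  # fitted cell means floored here so the CDF map stays defined


@dataclass
class BatchModel:
    """Fitted per-gene, per-batch NB distributions plus the batch-free target.

    With a saturated categorical design (batch x condition cells) the ML
    estimate of each cell mean under a log link is the cell's sample mean;
    dispersions are profile-ML per (gene, batch) given those means.
    """

    gene_ids: list
    sample_ids: list
    batches: list
    conditions: list
    mu: np.ndarray            # (G, n_batches, n_conditions)
    alpha: np.ndarray         # (G, n_batches)
    mu_target: np.ndarray     # (G, n_conditions)
    alpha_target: np.ndarray  # (G,)
    excluded: np.ndarray      # (G,) bool — all-zero in some batch, passed through
    ml_converged: np.ndarray  # (G, n_batches) bool — False where MoM fallback used
    batch_of_sample: dict
    condition_of_sample: dict
    include_condition: bool


def fit_batch_model(counts: CountMatrix, meta: SampleMetadata,
                    include_condition: bool = True) -> BatchModel:
    """Fit per-(gene, batch) NB distributions and the pooled batch-free target.

    Genes with all-zero counts in any batch are flagged ``excluded`` (their
    batch distribution is unidentifiable) and later passed through unchanged.
    Raises if any batch has fewer than two samples (dispersion unestimable).
    """
    meta.check_against(counts)
    batches = meta.batches
    conditions = (sorted(set(meta.table["condition"]))
                  if include_condition else ["all"])
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    G = len(counts.gene_ids)
    Y = counts.counts.astype(float)

    batch_cols = {}
    for b in batches:
        sids = list(meta.table.loc[meta.table["batch"] == b, "sample_id"])
        if len(sids) < 2:
            raise ValidationError(f"batch {b!r} has {len(sids)} sample(s); "
                                  "need >= 2 to estimate dispersion")
        batch_cols[b] = [col[s] for s in sids]

    cond_of = meta.condition_of_sample() if include_condition else {
        s: "all" for s in counts.sample_ids}

    mu = np.zeros((G, len(batches), len(conditions)))
    alpha = np.zeros((G, len(batches)))
    ml_converged = np.ones((G, len(batches)), dtype=bool)
    excluded = np.zeros(G, dtype=bool)

    for bi, b in enumerate(batches):
        cols_b = batch_cols[b]
        Yb = Y[:, cols_b]
        excluded |= (Yb.sum(axis=1) == 0)
        mu_b_full = np.empty_like(Yb)
        for ci, c in enumerate(conditions):
            cell = [j for j in cols_b if cond_of[counts.sample_ids[j]] == c]
            if cell:
                cell_mean = Y[:, cell].mean(axis=1)
            else:  # condition absent from this batch: use the batch mean
                cell_mean = Yb.mean(axis=1)
            mu[:, bi, ci] = np.maximum(cell_mean, MEAN_FLOOR)
        cond_idx = [conditions.index(cond_of[counts.sample_ids[j]]) for j in cols_b]
        for k, ci in enumerate(cond_idx):
            mu_b_full[:, k] = mu[:, bi, ci]
        a_hat, at_bound = fit_alpha_ml(Yb, mu_b_full)
        # method-of-moments fallback where ML pinned itself to the search bound
        resid = (Yb - mu_b_full) ** 2 - mu_b_full
        mom = np.clip(resid.sum(axis=1) / np.maximum((mu_b_full ** 2).sum(axis=1), 1e-12),
                      1e-8, 50.0)
        hit_hi = a_hat >= 50.0 * 0.95
        a_hat = np.where(hit_hi, mom, a_hat)
        alpha[:, bi] = a_hat
        ml_converged[:, bi] = ~at_bound

    # batch-free target: pool batch fits weighting by per-batch sample count
    w = np.array([len(batch_cols[b]) for b in batches], dtype=float)
    w = w / w.sum()
    mu_target = np.maximum(np.tensordot(mu, w, axes=([1], [0])), MEAN_FLOOR)
    alpha_target = alpha @ w

    if excluded.any():
        logger.info("batch model: %d gene(s) all-zero in some batch, excluded "
                    "from adjustment", int(excluded.sum()))

    return BatchModel(
        gene_ids=list(counts.gene_ids), sample_ids=list(counts.sample_ids),
        batches=batches, conditions=conditions, mu=mu, alpha=alpha,
        mu_target=mu_target, alpha_target=alpha_target, excluded=excluded,
        ml_converged=ml_converged, batch_of_sample=meta.batch_of_sample(),
        condition_of_sample=cond_of, include_condition=include_condition,
    )


def adjust_counts(counts: CountMatrix, model: BatchModel) -> CountMatrix:
    """Quantile-map each count to the batch-free target distribution.

    For count y in batch b the midpoint percentile p = (F_gb(y-1) + F_gb(y))/2
    under the fitted batch NB is carried to the target NB: the adjusted count
    is the smallest integer q with F*(q) >= p. Monotone in y; exact identity
    when source and target distributions coincide (e.g. single-batch input).
    """
    if list(counts.gene_ids) != list(model.gene_ids):
        raise ValidationError("count matrix genes do not match the fitted model")
    if set(counts.sample_ids) - set(model.sample_ids):
        raise ValidationError("count matrix contains samples absent from the model")

    out = counts.counts.copy()
    b_index = {b: i for i, b in enumerate(model.batches)}
    c_index = {c: i for i, c in enumerate(model.conditions)}
    active = ~model.excluded
    if not active.any():
        return CountMatrix(list(counts.gene_ids), list(counts.sample_ids), out)

    for j, s in enumerate(counts.sample_ids):
        bi = b_index[model.batch_of_sample[s]]
        ci = c_index[model.condition_of_sample[s]]
        y = counts.counts[active, j].astype(float)
        mu_b = model.mu[active, bi, ci]
        a_b = model.alpha[active, bi]
        mu_t = model.mu_target[active, ci]
        a_t = model.alpha_target[active]
        # when source and target distributions coincide the map is the
        # identity; short-circuit so single-batch input is reproduced exactly
        same = (mu_b == mu_t) & (a_b == a_t)
        p = 0.5 * (nb_cdf(y - 1.0, mu_b, a_b) + nb_cdf(y, mu_b, a_b))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        q = nb_ppf(p, mu_t, a_t)
        out[active, j] = np.where(same, y, q).astype(np.int64)

    return CountMatrix(list(counts.gene_ids), list(counts.sample_ids), out)
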