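"""TPM normalization and temporal z-score profiles.

Selected genes are converted to transcripts-per-million using annotation
lengths, collapsed to per-timepoint medians across replicates (robust to
outlier replicates), and z-scored per gene across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, SampleMetadata, ValidationError


def tpm(counts: CountMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """TPM_gj = (c_gj / L_g) / sum_h (c_hj / L_h) * 1e6; columns sum to 1e6."""
    lengths = annotation.lengths_for(counts.gene_ids)
    rates = counts.counts / lengths[:, None]
    colsum = rates.sum(axis=0)
    if (colsum == 0).any():
        bad = [s for s, c in zip(counts.sample_ids, colsum) if c == 0]
        raise ValidationError(f"all-zero sample column(s): {bad}")
    mat = rates / colsum[None, :] * 1e6
    return pd.DataFrame(mat, index=counts.gene_ids, columns=counts.sample_ids)


def median_profiles(tpm_matrix: pd.DataFrame, meta: SampleMetadata) -> pd.DataFrame:
    """Collapse replicate columns to the per-timepoint median, columns in
    developmental order."""
    cols = {}
    for tp in meta.timepoints:
        samples = [s for s in meta.samples_at(tp) if s in tpm_matrix.columns]
        if not samples:
            raise ValidationError(f"timepoint {tp!r} has no samples in the matrix")
        cols[tp] = tpm_matrix[samples].median(axis=1)
    return pd.DataFrame(cols, index=tpm_matrix.index)


@dataclass
class ProfileMatrix:
    """Gene x timepoint z-scores with pre-z mean/sd kept for traceability."""

    zscores: pd.DataFrame
    pre_mean: pd.Series
    pre_sd: pd.Series
    constant: pd.Series  # bool: flat genes, zeroed rather than dropped

    @property
    def timepoints(self) -> list[str]:
        return list(self.zscores.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.zscores.index)

    def values(self) -> np.ndarray:
        return self.zscores.to_numpy()


def zscore_profiles(profiles: pd.DataFrame, ddof: int = 1) -> ProfileMatrix:
    """Per-gene z = (x - mean)/sd across timepoints (sample sd by default).

    Constant genes are flagged and set to an all-zero profile rather than
    dropped, so cluster membership accounting matches the selected gene count.
    """
    if profiles.shape[1] < 2:
        raise ValidationError("need >= 2 timepoints to z-score profiles")
    X = profiles.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=ddof)
    constant = sd == 0
    safe_sd = np.where(constant, 1.0, sd)
    Z = (X - mean[:, None]) / safe_sd[:, None]
    Z[constant] = 0.0
    return ProfileMatrix(
        zscores=pd.DataFrame(Z, index=profiles.index, columns=profiles.columns),
        pre_mean=pd.Series(mean, index=profiles.index),
        pre_sd=pd.Series(sd, index=profiles.index),
        constant=pd.Series(constant, index=profiles.index),
    )
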