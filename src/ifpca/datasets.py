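"""Published benchmark numbers used as worked-example inputs.

These are the printed per-data-set clustering results of the comparison
study this package's evaluation harness mirrors: clustering-error counts
for ten gene microarray data sets, and clustering accuracies / adjusted
Rand indices for eight single-cell RNA-seq data sets.  They are inputs for
the rank/regret aggregation (`metrics.summarize`), not outputs of this
package; SC3's missing Patel value is the reason its column must be
excluded from ranking.

The underlying expression matrices are deposited at
https://data.mendeley.com/datasets/cdsz2ddv3t (microarray) and
https://data.mendeley.com/drafts/nv2x6kf5rd (single-cell) and are never
required by this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import ErrorTable

MICROARRAY_METHODS = [
    "k-means", "SpecGem", "IF-PCA", "IF-PCA(X)",
    "VAE", "VAE(X)", "IF-VAE", "IF-VAE(X)",
]

_MICROARRAY_ERRORS = {
    "Brain":            [14, 6, 11, 7, 14, 17, 21, 21],
    "Breast cancer":    [121, 121, 112, 91, 105, 130, 120, 118],
    "Colon cancer":     [28, 30, 25, 26, 29, 23, 25, 25],
    "Leukemia":         [2, 21, 5, 3, 28, 17, 20, 12],
    "Lung cancer (1)":  [18, 22, 5, 24, 21, 64, 6, 7],
    "Lung cancer (2)":  [44, 88, 44, 45, 66, 80, 44, 44],
    "Lymphoma":         [1, 14, 1, 18, 23, 22, 16, 10],
    "Prostate cancer":  [43, 43, 39, 44, 41, 45, 42, 41],
    "SRBCT":            [28, 32, 28, 24, 33, 26, 30, 23],
    "Su cancer":        [83, 85, 58, 57, 62, 60, 57, 57],
}

SINGLECELL_METHODS = [
    "Seurat", "SC3", "SC3(NGF)", "IF-PCA", "IF-PCA(X)", "IF-VAE", "IF-VAE(X)",
]

_SINGLECELL_ACCURACY = {
    "Camp1":    [0.637, 0.750, 0.627, 0.738, 0.736, 0.660, 0.700],
    "Camp2":    [0.661, 0.713, 0.759, 0.601, 0.656, 0.393, 0.491],
    "Darmanis": [0.682, 0.826, 0.867, 0.635, 0.747, 0.406, 0.617],
    "Deng":     [0.530, 0.590, 0.754, 0.791, 0.588, 0.607, 0.687],
    "Goolam":   [0.621, 0.758, 0.629, 0.637, 0.700, 0.612, 0.703],
    "Grun":     [0.994, 0.509, 0.511, 0.740, 0.657, 0.595, 0.753],
    "Li":       [0.934, 0.938, 0.980, 0.889, 0.968, 0.848, 0.853],
    "Patel":    [0.898, np.nan, 0.995, 0.795, 0.934, 0.325, 0.465],
}

_SINGLECELL_ARI = {
    "Camp1":    [0.534, 0.768, 0.526, 0.628, 0.627, 0.606, 0.615],
    "Camp2":    [0.443, 0.577, 0.502, 0.410, 0.493, 0.162, 0.304],
    "Darmanis": [0.480, 0.682, 0.784, 0.489, 0.650, 0.219, 0.525],
    "Deng":     [0.442, 0.646, 0.669, 0.771, 0.477, 0.487, 0.555],
    "Goolam":   [0.543, 0.687, 0.544, 0.356, 0.562, 0.410, 0.534],
    "Grun":     [0.969, -0.066, -0.060, 0.135, 0.102, 0.023, 0.137],
    "Li":       [0.904, 0.951, 0.968, 0.797, 0.940, 0.798, 0.792],
    "Patel":    [0.790, np.nan, 0.989, 0.598, 0.850, 0.173, 0.235],
}


def microarray_error_table() -> ErrorTable:
    """Clustering-error counts of 8 methods on 10 microarray data sets."""
    df = pd.DataFrame.from_dict(
        _MICROARRAY_ERRORS, orient="index", columns=MICROARRAY_METHODS
    )
    return ErrorTable(values=df, value_kind="errors")


def singlecell_accuracy_table() -> ErrorTable:
    """Clustering accuracies of 7 methods on 8 scRNA-seq data sets
    (SC3 is NA on Patel)."""
    df = pd.DataFrame.from_dict(
        _SINGLECELL_ACCURACY, orient="index", columns=SINGLECELL_METHODS
    )
    return ErrorTable(values=df, value_kind="accuracy")


def singlecell_ari_table() -> ErrorTable:
    """Adjusted Rand indices for the same methods/data sets."""
    df = pd.DataFrame.from_dict(
        _SINGLECELL_ARI, orient="index", columns=SINGLECELL_METHODS
    )
    return ErrorTable(values=df, value_kind="accuracy")
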