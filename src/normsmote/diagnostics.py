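"""Distribution-preservation diagnostics for oversampled data.

Two summary statistics, both computed in normalized feature space, quantify
how much an expansion distorted the original data's geometry:

* **inter-class distance** — Euclidean distance between the per-class feature
  centroids; oversampling toward the minority centroid should leave it nearly
  unchanged.
* **sample variance** — mean over features of the per-feature sample variance
  (n-1 denominator), over either all rows or the minority rows only.
  Centroid-directed synthesis shrinks it, more so for smaller spread scales,
  so its deviation from the original value ranks candidate sigma scales.

The spread scale whose expanded data deviates least from the original is the
recommended setting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import Dataset, ValidationError, normalize, partition_by_class
from .oversampling import ExpansionResult

__all__ = ["inter_class_distance", "sample_variance", "preservation_comparison"]


def inter_class_distance(d: Dataset) -> float:
    """Euclidean distance between minority and majority feature centroids."""
    part = partition_by_class(d)
    if part.minority.shape[0] == 0 or part.majority.shape[0] == 0:
        raise ValidationError("both classes must be non-empty")
    return float(np.linalg.norm(part.minority.mean(axis=0) - part.majority.mean(axis=0)))


def sample_variance(d: Dataset, scope: str = "all") -> float:
    """Mean over features of the per-feature sample variance (ddof=1)."""
    if scope == "all":
        rows = d.features
    elif scope == "minority":
        rows = partition_by_class(d).minority
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    if rows.shape[0] < 2:
        raise ValidationError("need >= 2 rows in scope for a variance estimate")
    return float(rows.var(axis=0, ddof=1).mean())


def preservation_comparison(
    original: Dataset,
    expansions,
    labels=None,
    scope: str = "all",
) -> pd.DataFrame:
    """Tabulate both diagnostics for the original data and each expansion.

    Parameters
    ----------
    original : Dataset
        The unexpanded data in original units; it is normalized here.
    expansions : sequence of ExpansionResult or Dataset
        Expanded datasets to compare; either ExpansionResult objects (their
        fused datasets are used) or Datasets already in normalized space.
    labels : sequence of str, optional
        Row labels for the expansions (e.g. sigma-scale names).
    scope : {"all", "minority"}
        Row scope of the sample-variance statistic.

    Returns
    -------
    DataFrame with one row per input, columns ``inter_class_distance``,
    ``sample_variance``, their absolute deviations from the original row, and
    boolean ``best_*`` flags marking the expansion minimizing each deviation.
    """
    normalized, _ = normalize(original)
    rows = [
        {
            "dataset": "original",
            "inter_class_distance": inter_class_distance(normalized),
            "sample_variance": sample_variance(normalized, scope),
        }
    ]
    expansions = list(expansions)
    if labels is None:
        labels = [
            str(e.provenance.get("config", {}).get("sigma_scale", e.provenance.get("method", i)))
            if isinstance(e, ExpansionResult)
            else f"expanded_{i}"
            for i, e in enumerate(expansions)
        ]
    for name, exp in zip(labels, expansions):
        if isinstance(exp, ExpansionResult):
            fused = exp.fused
        elif isinstance(exp, Dataset):
            fused = exp
        else:
            raise ValidationError("expansions must be ExpansionResult or Dataset objects")
        rows.append(
            {
                "dataset": str(name),
                "inter_class_distance": inter_class_distance(fused),
                "sample_variance": sample_variance(fused, scope),
            }
        )
    table = pd.DataFrame(rows).set_index("dataset")
    for col in ("inter_class_distance", "sample_variance"):
        table[f"{col}_deviation"] = (table[col] - table.loc["original", col]).abs()
        flag = pd.Series(False, index=table.index)
        if expansions:
            flag[table[f"{col}_deviation"].iloc[1:].idxmin()] = True
        table[f"best_{col}"] = flag
    return table
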