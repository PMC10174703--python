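"""Reading and writing wide intensity matrices and result tables.

Input tables are rectangular: a header row of sample ids and a first
column of feature ids.  Dialects differ in how missing values are
encoded — empty cells / ``NA`` (the default) or zeros (MaxQuant-style
output, where a reported 0 means "not detected", never a measured
intensity).  Zero-as-missing and a minimum-intensity floor are applied on
the raw scale, before any log2 transform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix

__all__ = ["MatrixDialect", "read_matrix", "write_matrix", "write_truth",
           "write_results", "write_fit_json"]


@dataclass(frozen=True)
class MatrixDialect:
    """How a wide intensity table encodes its values.

    ``missing_encoding`` is one of ``"empty"`` (empty cell or NA), or
    ``"zero"`` (0 means missing).  ``transform="log2"`` log2-transforms
    values after missingness decoding; ``min_intensity`` (raw scale) floors
    detection — values strictly below it become missing.
    """

    missing_encoding: str = "empty"
    transform: str = "none"
    min_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.missing_encoding not in ("empty", "zero"):
            raise ValueError("missing_encoding must be 'empty' or 'zero'")
        if self.transform not in ("none", "log2"):
            raise ValueError("transform must be 'none' or 'log2'")


def read_matrix(path, dialect: MatrixDialect = MatrixDialect(),
                drop_empty: bool = True, sep: str | None = None,
                ) -> tuple[IntensityMatrix, int]:
    """Read a wide feature-by-sample table into an :class:`IntensityMatrix`.

    Returns ``(matrix, n_dropped)`` where ``n_dropped`` counts features
    removed for being missing in every sample (only when ``drop_empty``).
    The separator is sniffed from the extension unless given.
    """
    path = str(path)
    if sep is None:
        sep = "," if path.endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#",
                        na_values=["NA", "NaN", "nan"], keep_default_na=True,
                        float_precision="round_trip")
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(frame.columns):
            bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"non-numeric cell at feature {frame.index[i]!r}, "
                    f"sample {col!r}: {frame[col].iloc[i]!r}"
                ) from exc
        raise
    mask = np.isfinite(values)
    if dialect.missing_encoding == "zero":
        mask &= values != 0
    if dialect.min_intensity is not None:
        mask &= ~(values < dialect.min_intensity)
    if dialect.transform == "log2":
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(mask & (values > 0), np.log2(np.where(values > 0, values, 1.0)), np.nan)
        mask &= np.isfinite(values)
    values = np.where(mask, values, np.nan)
    mat = IntensityMatrix(values, mask.astype(np.int8),
                          [str(i) for i in frame.index],
                          [str(c) for c in frame.columns])
    n_dropped = 0
    if drop_empty:
        mat, n_dropped = mat.drop_empty_features()
    return mat, n_dropped


def _header_comment(config_hash: str | None = None) -> str:
    from . import __version__

    h = f" config={config_hash}" if config_hash else ""
    return f"# protdpc v{__version__}{h}\n"


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str)
                          .encode()).hexdigest()[:12]


def write_matrix(path, data: IntensityMatrix, sep: str = "\t",
                 config_hash: str | None = None) -> None:
    """Write a wide TSV/CSV with empty cells for missing entries."""
    frame = pd.DataFrame(np.where(data.mask == 1, data.values, np.nan),
                         index=data.feature_ids, columns=data.sample_ids)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        frame.to_csv(fh, sep=sep, na_rep="")


def write_truth(path, dataset, sep: str = "\t",
                config_hash: str | None = None) -> None:
    """Sidecar TSV with the simulation truth per feature."""
    frame = pd.DataFrame(
        {
            "feature_id": dataset.complete.feature_ids,
            "de_label": dataset.de_labels,
            "true_mean": dataset.true_means,
        }
    )
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        frame.to_csv(fh, sep=sep, index=False)


def write_results(path, results, sep: str = "\t",
                  config_hash: str | None = None) -> None:
    """Write a differential-expression result table."""
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        results.table.to_csv(fh, sep=sep, index=False, na_rep="NA",
                             float_format="%.6g")


def write_fit_json(path, fit, config_hash: str | None = None) -> None:
    """Serialise a DPC fit to JSON."""
    from . import __version__

    payload = {"tool": "protdpc", "version": __version__}
    if config_hash:
        payload["config_hash"] = config_hash
    payload.update(fit.to_dict())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
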