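"""Reading and writing the delimiter-separated table formats.

The data matrix is samples x features with a header row of feature ids;
labels are either a designated column of the matrix file or a separate
single-column file.  Labels must be coded {0, 1}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def load_matrix(path, label_col: str | None = None, labels_path=None, sep: str = "\t"):
    """Load (X, y, feature_names) from text tables.

    Exactly one of ``label_col`` (column of the matrix file) or
    ``labels_path`` (separate single-column file with header) must be
    given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep=sep)
    if (label_col is None) == (labels_path is None):
        raise ValueError("give exactly one of label_col or labels_path")
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in {path}")
        y = df[label_col].to_numpy()
        df = df.drop(columns=[label_col])
    else:
        labels_path = Path(labels_path)
        if not labels_path.exists():
            raise FileNotFoundError(f"labels file not found: {labels_path}")
        y = pd.read_csv(labels_path, sep=sep).iloc[:, 0].to_numpy()
    if len(y) != len(df):
        raise ValueError("label count does not match sample count")
    if not set(np.unique(y).tolist()) <= {0, 1}:
        raise ValueError("labels must be coded {0, 1}")
    return df.to_numpy(dtype=np.float64), y.astype(np.int64), list(df.columns)


def save_matrix(path, X, feature_names=None, y=None, label_col="label", sep: str = "\t"):
    X = np.asarray(X)
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names)
    if y is not None:
        df[label_col] = np.asarray(y)
    df.to_csv(path, sep=sep, index=False)


def write_metadata(path, **fields) -> None:
    """Run-metadata sidecar (seeds, parameters, versions) as JSON."""
    import sklearn

    meta = {
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        **fields,
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
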