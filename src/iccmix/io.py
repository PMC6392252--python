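"""Reading/writing datasets and models; train/test splitting.

Datasets travel as delimited text with a header row: one numeric response
column (default ``y``) and numeric feature columns ``x1..xp``. Simulated
datasets carry a JSON truth sidecar (memberships, true coefficients,
sigmas, mixing proportions) written next to the CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Dataset, Truth

__all__ = [
    "read_table",
    "write_dataset",
    "read_dataset",
    "split_train_test",
    "save_model",
    "load_model",
]


def read_table(path, response_name: str = "y") -> Dataset:
    """Load a dataset from delimited text.

    The file must have a header, a numeric response column named
    ``response_name`` and numeric feature columns. Missing or non-numeric
    cells are rejected with row/column diagnostics; duplicated column
    names are an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    dup = sorted({c for c in header if header.count(c) > 1})
    if dup:
        raise ValueError(f"duplicated column names: {dup}")
    df = pd.read_csv(path)
    if response_name not in df.columns:
        raise ValueError(f"response column {response_name!r} not found in {path.name}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"missing or non-numeric value at row {row + 2} "  # 1-based + header
                f"column {col!r} of {path.name}"
            )
        df[col] = vals
    y = df.pop(response_name).to_numpy(dtype=float)
    X = df.to_numpy(dtype=float)
    return Dataset(X=X, y=y, feature_names=list(df.columns))


def write_dataset(dataset: Dataset, csv_path, truth_path=None) -> None:
    """Write the data CSV (response column ``y`` first, features after) and,
    when ground truth is attached, a JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    df.insert(0, "y", dataset.y)
    df.to_csv(csv_path, index=False)
    if dataset.truth is not None:
        if truth_path is None:
            truth_path = csv_path.with_suffix(".truth.json")
        t = dataset.truth
        payload = {
            "memberships": t.memberships.tolist(),
            "betas": [
                {"intercept": float(b[0]),
                 "coefficients": {str(j): float(v)
                                  for j, v in enumerate(b[1:]) if v != 0}}
                for b in t.betas
            ],
            "sigma": t.sigma.tolist(),
            "pi": t.pi.tolist(),
            "mu": np.asarray(t.mu).tolist(),
        }
        Path(truth_path).write_text(json.dumps(payload))


def read_dataset(csv_path, truth_path=None, response_name: str = "y") -> Dataset:
    """Read a CSV (and its truth sidecar when present) back into a Dataset."""
    csv_path = Path(csv_path)
    dataset = read_table(csv_path, response_name)
    if truth_path is None:
        truth_path = csv_path.with_suffix(".truth.json")
    truth_path = Path(truth_path)
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        p = dataset.p
        betas = []
        for b in payload["betas"]:
            vec = np.zeros(p + 1)
            vec[0] = b["intercept"]
            for j, v in b["coefficients"].items():
                vec[int(j) + 1] = v
            betas.append(vec)
        dataset.truth = Truth(
            memberships=np.asarray(payload["memberships"], dtype=np.intp),
            betas=betas,
            sigma=np.asarray(payload["sigma"], dtype=float),
            pi=np.asarray(payload["pi"], dtype=float),
            mu=np.asarray(payload["mu"], dtype=float),
        )
    return dataset


def split_train_test(dataset: Dataset, fraction: float = 0.8,
                     scheme: str = "in-order", seed: int | None = None,
                     n_folds: int = 5):
    """Split a dataset for out-of-sample evaluation.

    ``in-order`` takes the first ceil(fraction * n) rows as training (the
    convention for data distributed in a fixed published order);
    ``shuffled`` permutes rows with *seed* first; ``k-fold`` returns a list
    of (train, test) Dataset pairs from ``n_folds`` disjoint folds.
    """
    n = dataset.n
    if scheme == "k-fold":
        from sklearn.model_selection import KFold

        kf = KFold(n_splits=n_folds, shuffle=seed is not None, random_state=seed)
        return [
            (dataset.subset(tr), dataset.subset(te))
            for tr, te in kf.split(np.arange(n))
        ]
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(np.ceil(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"n={n} too small to split at fraction {fraction}")
    order = np.arange(n)
    if scheme == "shuffled":
        order = np.random.default_rng(seed).permutation(n)
    elif scheme != "in-order":
        raise ValueError("scheme must be 'in-order', 'shuffled' or 'k-fold'")
    return dataset.subset(order[:n_train]), dataset.subset(order[n_train:])


def save_model(model, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path):
    from .icc import MixtureModel

    return MixtureModel.from_json(Path(path).read_text())
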