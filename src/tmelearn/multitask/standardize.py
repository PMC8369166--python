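"""Train-statistics standardization.

Test data is always transformed with the mean and standard deviation of the
training set, never its own.  Constant training columns transform to zero
and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Standardizer:
    mean: np.ndarray = field(default=None)
    sd: np.ndarray = field(default=None)
    constant: np.ndarray = field(default=None)  # bool per column

    def fit(self, train: np.ndarray) -> "Standardizer":
        train = np.asarray(train, dtype=float)
        if train.size == 0:
            raise ValueError("cannot fit a standardizer on empty data")
        self.mean = train.mean(axis=0)
        self.sd = train.std(axis=0)
        self.constant = self.sd == 0
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        sd_safe = np.where(self.constant, 1.0, self.sd)
        out = (data - self.mean) / sd_safe
        out[:, self.constant] = 0.0
        return out

    def fit_transform(self, train: np.ndarray) -> np.ndarray:
        return self.fit(train).transform(train)

    def inverse_transform(self, data: np.ndarray) -> np.ndarray:
        return np.asarray(data, dtype=float) * np.where(self.constant, 0.0, self.sd) + self.mean

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "constant": self.constant.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        for key in ("mean", "sd", "constant"):
            if key not in d:
                raise ValueError(f"serialized standardizer missing {key!r}")
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            constant=np.asarray(d["constant"], dtype=bool),
        )
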