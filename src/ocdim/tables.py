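"""Shared result tables used across estimation modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"


@dataclass
class PersonScoreTable:
    """Per-person latent-trait point estimates with posterior SDs.

    ``mean`` is the posterior (EAP) mean of the person's latent propensity on
    the population metric (mean 0, SD 1); ``sd`` is the posterior SD, which
    serves as the score's standard error. ``flags`` marks persons whose score
    rests on little or no observed data (all-zero responders, persons with no
    administered ratings).
    """

    person_ids: list
    mean: np.ndarray
    sd: np.ndarray
    flags: dict = field(default_factory=dict)  # person_id -> reason string

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        n = len(self.person_ids)
        if self.mean.shape != (n,) or self.sd.shape != (n,):
            raise ValueError("mean/sd length must match person_ids")

    def __len__(self):
        return len(self.person_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person_id": self.person_ids,
                "score": self.mean,
                "se": self.sd,
                "flag": [self.flags.get(p, "") for p in self.person_ids],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)

    @classmethod
    def read(cls, path) -> "PersonScoreTable":
        df = pd.read_csv(path, keep_default_na=False, dtype={"person_id": str})
        flags = {
            p: f for p, f in zip(df["person_id"], df["flag"].astype(str)) if f
        }
        return cls(
            person_ids=list(df["person_id"]),
            mean=df["score"].astype(float).to_numpy(),
            sd=df["se"].astype(float).to_numpy(),
            flags=flags,
        )
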