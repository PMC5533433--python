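"""Sampled pressure/flow/area time series at a named site."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .units import MMHG

__all__ = ["WaveRecord", "read_record_csv", "write_records_h5"]


@dataclass
class WaveRecord:
    """One converged-cycle recording at a measurement site.

    ``t`` is a uniform grid spanning exactly one cardiac period with an
    exclusive right endpoint (t[0] = 0, t[-1] = T - dt), so time averages
    are plain means and FFTs see exactly one period.  P in Pa, Q in m^3/s,
    A in m^2.
    """

    site: str
    t: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray | None = None
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        if len(self.P) != n or len(self.Q) != n or (self.A is not None and len(self.A) != n):
            raise ValueError("t, P, Q, A must have equal length")

    @property
    def period(self) -> float:
        return float(self.t[-1] + (self.t[1] - self.t[0]))

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.t,
            "pressure_mmHg": self.P / MMHG,
            "flow_ml_s": self.Q * 1e6,
        })
        df["area_cm2"] = self.A * 1e4 if self.A is not None else np.nan
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def read_record_csv(path, site: str | None = None) -> WaveRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "pressure_mmHg", "flow_ml_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    area = df["area_cm2"].to_numpy() * 1e-4 if "area_cm2" in df.columns else None
    if area is not None and np.all(np.isnan(area)):
        area = None
    return WaveRecord(
        site=site or Path(str(path)).stem,
        t=df["time_s"].to_numpy(),
        P=df["pressure_mmHg"].to_numpy() * MMHG,
        Q=df["flow_ml_s"].to_numpy() * 1e-6,
        A=area,
    )


def write_records_h5(records: dict[str, WaveRecord], path) -> None:
    """Bundle all site records into one HDF5 file (SI units)."""
    import h5py

    with h5py.File(path, "w") as f:
        for site, rec in records.items():
            g = f.create_group(site)
            g.create_dataset("t", data=rec.t)
            g.create_dataset("P", data=rec.P)
            g.create_dataset("Q", data=rec.Q)
            if rec.A is not None:
                g.create_dataset("A", data=rec.A)
            g.attrs["converged"] = rec.converged
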