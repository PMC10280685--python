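"""Observed-data container for joint RA/RT analyses.

Data are wide matrices: N persons in rows, K items in columns.  Accuracy is
binary (0/1) with ``NaN`` for missing; response times are stored on the log
scale with ``NaN`` for missing.  Two kinds of missingness are distinguished:
*missing by design* (cells never administered because of the test booklet
structure; excluded from every likelihood term and never imputed) and
*missing at random* (imputed each MCMC iteration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TestData"]


@dataclass
class TestData:
    """N x K accuracy and log-RT matrices with missingness bookkeeping.

    Parameters
    ----------
    y : ndarray
        Binary accuracy matrix, ``NaN`` for missing.
    log_rt : ndarray
        Log response-time matrix, ``NaN`` for missing.
    mbd_y, mbd_rt : ndarray of bool, optional
        ``True`` marks a cell that is missing by design.  By-design cells
        must be ``NaN`` in the corresponding data matrix.
    """

    y: np.ndarray
    log_rt: np.ndarray
    mbd_y: np.ndarray | None = field(default=None)
    mbd_rt: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.log_rt = np.asarray(self.log_rt, dtype=float)
        if self.y.ndim != 2 or self.log_rt.ndim != 2:
            raise ValueError("y and log_rt must be 2-d (persons x items)")
        if self.y.shape != self.log_rt.shape:
            raise ValueError(
                f"shape mismatch: y {self.y.shape} vs log_rt {self.log_rt.shape}"
            )
        vals = self.y[~np.isnan(self.y)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("y must contain only 0, 1 or missing values")
        for name in ("mbd_y", "mbd_rt"):
            m = getattr(self, name)
            if m is None:
                setattr(self, name, np.zeros(self.y.shape, dtype=bool))
            else:
                m = np.asarray(m, dtype=bool)
                if m.shape != self.y.shape:
                    raise ValueError(f"{name} shape {m.shape} != data shape {self.y.shape}")
                setattr(self, name, m)
        # a by-design cell carries no observation
        self.y = np.where(self.mbd_y, np.nan, self.y)
        self.log_rt = np.where(self.mbd_rt, np.nan, self.log_rt)

    @property
    def n_persons(self) -> int:
        return self.y.shape[0]

    @property
    def n_items(self) -> int:
        return self.y.shape[1]

    @property
    def observed_y(self) -> np.ndarray:
        """Cells with an actual accuracy observation."""
        return ~np.isnan(self.y) & ~self.mbd_y

    @property
    def observed_rt(self) -> np.ndarray:
        return ~np.isnan(self.log_rt) & ~self.mbd_rt

    @property
    def mar_y(self) -> np.ndarray:
        """Accuracy cells missing at random (imputed during sampling)."""
        return np.isnan(self.y) & ~self.mbd_y

    @property
    def mar_rt(self) -> np.ndarray:
        return np.isnan(self.log_rt) & ~self.mbd_rt

    def validate_for_fit(self, allow_empty_records: bool = False) -> None:
        """Reject rows/columns with no usable information.

        A person (or item) contributing no observed accuracy *and* no
        observed RT cell is rejected unless all of its missing cells are
        covered by missing-by-design masks, or ``allow_empty_records`` is
        set (the differential-speed model draws such records from the
        population model).
        """
        obs = self.observed_y | self.observed_rt
        mbd_all = self.mbd_y & self.mbd_rt
        for axis, label in ((1, "row"), (0, "column")):
            empty = ~obs.any(axis=axis)
            covered = mbd_all.all(axis=axis)
            bad = np.nonzero(empty & ~covered)[0]
            if bad.size and not allow_empty_records:
                raise ValueError(
                    f"{label}(s) {bad.tolist()} have no observed cells and are not "
                    "missing by design; remove them or flag them in the design masks"
                )
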