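"""CSV/JSON input and output.

Data files are wide-format CSV: a header row of item labels and one row per
person; missing values are empty fields or ``NA``.  Chains are written as
one CSV per parameter block plus a JSON manifest recording the run
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import TestData

__all__ = [
    "read_matrix",
    "write_matrix",
    "load_test_data",
    "save_simulation",
    "save_draws",
    "save_fit_report",
    "config_to_json",
]

_NA = ["", "NA", "NaN", "nan"]


def read_matrix(path) -> np.ndarray:
    """Read a wide-format CSV matrix (header row, one row per person)."""
    df = pd.read_csv(path, na_values=_NA, keep_default_na=True)
    return df.to_numpy(dtype=float)


def write_matrix(arr: np.ndarray, path, prefix: str = "item") -> None:
    arr = np.atleast_2d(np.asarray(arr))
    cols = [f"{prefix}{j + 1}" for j in range(arr.shape[1])]
    pd.DataFrame(arr, columns=cols).to_csv(path, index=False, na_rep="NA")


def load_test_data(
    y_path,
    rt_path,
    mbdy_path=None,
    mbdt_path=None,
    raw_times: bool = False,
) -> TestData:
    """Assemble a :class:`TestData` from CSV files.

    With ``raw_times`` the RT file holds response times in seconds; they are
    log-transformed, and zero or negative entries become missing (their
    cause is unknown, so they are treated as missing at random).
    """
    y = read_matrix(y_path)
    rt = read_matrix(rt_path)
    if raw_times:
        with np.errstate(invalid="ignore", divide="ignore"):
            rt = np.where(rt > 0, np.log(np.clip(rt, 1e-300, None)), np.nan)

    def _mask(path):
        if path is None:
            return None
        return read_matrix(path) == 0  # 0 = missing by design

    return TestData(y=y, log_rt=rt, mbd_y=_mask(mbdy_path), mbd_rt=_mask(mbdt_path))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_to_json(config) -> dict:
    return _jsonable(config)


def save_simulation(truth, outdir) -> None:
    """Write a simulated dataset (data, truth, manifest) as CSV + JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(truth.data.y, out / "Y.csv")
    write_matrix(truth.data.log_rt, out / "RT.csv")
    if truth.data.mbd_y.any():
        write_matrix((~truth.data.mbd_y).astype(int), out / "MBDY.csv")
    if truth.data.mbd_rt.any():
        write_matrix((~truth.data.mbd_rt).astype(int), out / "MBDT.csv")
    items = pd.DataFrame(
        {
            "a": np.atleast_1d(truth.items.a),
            "b": np.atleast_1d(truth.items.b),
            "c": np.broadcast_to(truth.items.c, np.atleast_1d(truth.items.a).shape),
            "phi": np.broadcast_to(truth.items.phi, np.atleast_1d(truth.items.a).shape),
            "lam": np.broadcast_to(truth.items.lam, np.atleast_1d(truth.items.a).shape),
            "sigma2": np.broadcast_to(truth.items.sigma2, np.atleast_1d(truth.items.a).shape),
        }
    )
    items.to_csv(out / "items_truth.csv", index=False)
    persons = {"theta": np.atleast_1d(truth.persons.theta),
               "zeta": np.atleast_1d(truth.persons.zeta)}
    if truth.growth is not None:
        persons.update({k: truth.growth[k] for k in ("zeta0", "zeta1", "zeta2")})
    pd.DataFrame(persons).to_csv(out / "persons_truth.csv", index=False)
    manifest = {"kind": "simulation", "n": truth.data.n_persons, "k": truth.data.n_items}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def save_draws(draws, outdir) -> None:
    """Write chains as one CSV per parameter block plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    blocks = {
        "a": ("item", draws.a),
        "b": ("item", draws.b),
        "phi": ("item", draws.phi),
        "lam": ("item", draws.lam),
        "sigma2": ("item", draws.sigma2),
        "theta": ("person", draws.theta),
        "zeta": ("person", draws.zeta),
    }
    if hasattr(draws, "c"):
        blocks["c"] = ("item", draws.c)
    if hasattr(draws, "mu_p"):
        blocks["mu_p"] = ("col", draws.mu_p)
        blocks["sigma_p"] = ("col", draws.sigma_p.reshape(draws.sigma_p.shape[0], -1))
        blocks["mu_i"] = ("col", draws.mu_i)
        blocks["sigma_i"] = ("col", draws.sigma_i.reshape(draws.sigma_i.shape[0], -1))
    if hasattr(draws, "person_cov"):
        blocks["mu_theta"] = ("col", draws.mu_theta[:, None])
        blocks["person_cov"] = ("col", draws.person_cov.reshape(draws.person_cov.shape[0], -1))
        blocks["zeta"] = ("col", draws.zeta.reshape(draws.zeta.shape[0], -1))
    for name, (prefix, arr) in blocks.items():
        if arr.size:
            write_matrix(arr, out / f"chain_{name}.csv", prefix=prefix)
    manifest = {"kind": "chains", "config": config_to_json(draws.config)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def save_fit_report(report, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.person_table().to_csv(out / "person_fit.csv", index_label="person")
    report.item_table().to_csv(out / "item_fit.csv", index_label="item")
    write_matrix(report.eap_resid, out / "rt_residual_prob.csv")
    write_matrix(report.eap_resid_ra, out / "ra_residual_prob.csv")
    write_matrix(report.eap_l0, out / "ra_loglik_cell.csv")
    summary = {
        "n_draws": report.n_draws,
        "extreme_rt_fraction": report.extreme_rt_fraction(),
        "extreme_ra_fraction": report.extreme_ra_fraction(),
        "alpha": report.config.alpha,
        "c_resid": report.config.c_resid,
        "flag_probability": report.config.flag_probability,
    }
    (out / "fit_summary.json").write_text(json.dumps(summary, indent=2))
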