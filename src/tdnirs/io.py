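"""File formats: HDF5 TPSF container, extinction CSV, feature/report files.

The bulk photon histogram container is HDF5 with layout
``/tpsf/ch{CC}/wl{WWW}`` holding ``counts[frames, bins]``, ``bin_edges_ps``
and ``frame_times_s``.  Tabular outputs are UTF-8 CSV with '.' decimals;
CSV files written by a pipeline run carry the run's config hash in a
leading ``#`` comment line and are re-read with ``comment='#'``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .physics import ExtinctionTable, TPSFRecord


def write_tpsf_h5(path: Path | str, records: list[TPSFRecord]) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("tpsf")
        for rec in records:
            g = root.create_group(f"ch{rec.channel_id:02d}/wl{int(rec.wavelength_nm)}")
            g.create_dataset("counts", data=rec.counts, compression="gzip")
            g.create_dataset("bin_edges_ps", data=rec.bin_edges_ps)
            g.create_dataset("frame_times_s", data=rec.frame_times_s)


def read_tpsf_h5(path: Path | str) -> list[TPSFRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for ch_name, ch_grp in sorted(f["tpsf"].items()):
            for wl_name, g in sorted(ch_grp.items()):
                records.append(
                    TPSFRecord(
                        channel_id=int(ch_name.removeprefix("ch")),
                        wavelength_nm=float(wl_name.removeprefix("wl")),
                        bin_edges_ps=g["bin_edges_ps"][()],
                        counts=g["counts"][()],
                        frame_times_s=g["frame_times_s"][()],
                    )
                )
    return records


def extinction_to_csv(table: ExtinctionTable, path: Path | str) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": table.wavelengths_nm,
            "eps_HbO": table.eps_hbo,
            "eps_HbR": table.eps_hbr,
        }
    ).to_csv(path, index=False)


def extinction_from_csv(path: Path | str) -> ExtinctionTable:
    df = pd.read_csv(path)
    required = {"wavelength_nm", "eps_HbO", "eps_HbR"}
    if not required.issubset(df.columns):
        raise ValueError(f"extinction CSV must have columns {sorted(required)}")
    return ExtinctionTable(
        wavelengths_nm=tuple(df["wavelength_nm"].astype(float)),
        eps_hbo=tuple(df["eps_HbO"].astype(float)),
        eps_hbr=tuple(df["eps_HbR"].astype(float)),
    )


def write_csv(df: pd.DataFrame, path: Path | str, config_hash: str | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as f:
        if config_hash:
            f.write(f"# config_hash={config_hash}\n")
        df.to_csv(f, index=index)


def read_csv(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_report_json(report: dict, path: Path | str, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(report)
    if config_hash:
        payload["config_hash"] = config_hash
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
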