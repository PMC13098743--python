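"""Session-bundle readers and writers.

A session bundle is a directory: ``meta.json`` (ids, seed, probe geometry,
schema version), ``events.csv``, ``bloodgas.csv``, ``vitals.csv``, optional
``masks.csv``, and ``optical.h5`` holding the array-heavy raw optical data
(HDF5 groups /trs/<location>/{counts,timestamps,bin_width_ps,wavelengths,
irf} and /dcs/<location>/{tau,g2,count_rate_khz,timestamps}). All times are
seconds on the session clock. Numeric round trips are lossless; tabular
clinical data stay inspectable as CSV.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .biomarkers import BloodGasSample, HemoTrace, SubjectSession, VitalsTrace
from .inversion import DTOFRecord, G2Record, IRFRecord
from .qc import ArtifactMask
from .synthetic import InstrumentSpec, RawSessionBundle

__all__ = [
    "SCHEMA_VERSION",
    "BundleError",
    "write_bundle",
    "read_bundle",
    "write_processed",
    "read_processed",
    "load_reference_cohort",
]

SCHEMA_VERSION = "1"


class BundleError(ValueError):
    """A session bundle violates the expected schema."""


def _write_csv(df: pd.DataFrame, path) -> None:
    """CSV with repr-roundtrip float precision (lossless read-back)."""
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def load_reference_cohort(included_only: bool = False) -> pd.DataFrame:
    """The bundled reference transfusion-cohort demographics table."""
    ref = importlib.resources.files("hybriddo").joinpath(
        "data/cohort_demographics.csv"
    )
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#")
    df["included"] = df["included"] == "yes"
    if included_only:
        df = df[df["included"]].reset_index(drop=True)
    return df


def write_bundle(bundle: RawSessionBundle, path) -> None:
    """Serialize a raw session bundle to its canonical directory layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    inst = bundle.instrument
    meta = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": bundle.subject_id,
        "seed": bundle.seed,
        "trs_rho_mm": inst.trs_rho,
        "dcs_rho_mm": inst.dcs_rho,
        "n_tissue": inst.n_tissue,
        "n_outside": inst.n_outside,
        "wavelengths_nm": list(inst.wavelengths),
        "dcs_wavelength_nm": inst.dcs_wavelength,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))

    ev_rows = []
    for label, val in bundle.events.items():
        times = val if isinstance(val, (list, tuple, np.ndarray)) else [val]
        label_out = "blood_draw" if label == "blood_draws" else label
        ev_rows.extend({"time_s": float(t), "label": label_out} for t in times)
    _write_csv(pd.DataFrame(ev_rows).sort_values("time_s"), path / "events.csv")

    _write_csv(
        pd.DataFrame(
            [
                {
                    "time_s": s.time,
                    "period": s.period,
                    "hgb_gdl": s.hgb,
                    "hct_pct": s.hct,
                    "paco2_mmhg": s.paco2,
                    "hgbo2_gdl": s.hgbo2,
                    "hgbr_gdl": s.hgbr,
                }
                for s in bundle.bloodgas
            ]
        ),
        path / "bloodgas.csv",
    )

    v = bundle.vitals
    _write_csv(
        pd.DataFrame(
            {
                "time_s": v.timestamps,
                "sao2": v.sao2,
                "map_mmhg": v.map_mmhg,
                "hr_bpm": v.hr_bpm,
            }
        ),
        path / "vitals.csv",
    )

    if bundle.masks:
        rows = [
            {"t_start_s": a, "t_end_s": b, "source": m.source, "label": ""}
            for m in bundle.masks
            for a, b in m.intervals
        ]
        _write_csv(pd.DataFrame(rows), path / "masks.csv")

    with h5py.File(path / "optical.h5", "w") as h5:
        for loc in sorted({d.location for d in bundle.dtofs}):
            recs = [d for d in bundle.dtofs if d.location == loc]
            wavelengths = sorted({d.wavelength for d in recs})
            ts = sorted({d.timestamp for d in recs})
            n_bins = recs[0].counts.size
            counts = np.zeros((len(wavelengths), len(ts), n_bins), dtype=np.int64)
            ts_index = {t: j for j, t in enumerate(ts)}
            for d in recs:
                counts[wavelengths.index(d.wavelength), ts_index[d.timestamp]] = d.counts
            grp = h5.create_group(f"trs/{loc}")
            grp.create_dataset("counts", data=counts)
            grp.create_dataset("timestamps", data=np.array(ts, dtype=float))
            grp.create_dataset("bin_width_ps", data=float(recs[0].bin_width))
            grp.create_dataset("wavelengths", data=np.array(wavelengths, dtype=float))
            grp.create_dataset(
                "irf",
                data=np.stack([bundle.irfs[w].counts for w in wavelengths]),
            )
        for loc in sorted({g.location for g in bundle.g2s}):
            recs = sorted(
                (g for g in bundle.g2s if g.location == loc), key=lambda g: g.timestamp
            )
            grp = h5.create_group(f"dcs/{loc}")
            grp.create_dataset("tau", data=recs[0].tau)
            grp.create_dataset("g2", data=np.stack([g.g2 for g in recs]))
            grp.create_dataset(
                "count_rate_khz", data=np.array([g.count_rate for g in recs])
            )
            grp.create_dataset(
                "timestamps", data=np.array([g.timestamp for g in recs])
            )


def read_bundle(path) -> RawSessionBundle:
    """Load a session bundle; schema violations name the offending file."""
    path = Path(path)
    for required in ("meta.json", "events.csv", "bloodgas.csv", "vitals.csv",
                     "optical.h5"):
        if not (path / required).exists():
            raise BundleError(f"bundle {path} is missing required file {required}")
    meta = json.loads((path / "meta.json").read_text())
    for field_name in ("subject_id", "trs_rho_mm", "dcs_rho_mm"):
        if field_name not in meta:
            raise BundleError(f"meta.json lacks required field {field_name!r}")

    ev = pd.read_csv(path / "events.csv", float_precision="round_trip")
    events: dict = {"blood_draws": []}
    for _, row in ev.iterrows():
        if row["label"] == "blood_draw":
            events["blood_draws"].append(float(row["time_s"]))
        else:
            events[row["label"]] = float(row["time_s"])

    bg = pd.read_csv(path / "bloodgas.csv", float_precision="round_trip")
    bloodgas = [
        BloodGasSample(
            time=float(r["time_s"]),
            hgb=float(r["hgb_gdl"]),
            hct=float(r["hct_pct"]),
            paco2=float(r["paco2_mmhg"]),
            period=str(r["period"]),
            hgbo2=None if pd.isna(r.get("hgbo2_gdl")) else float(r["hgbo2_gdl"]),
            hgbr=None if pd.isna(r.get("hgbr_gdl")) else float(r["hgbr_gdl"]),
        )
        for _, r in bg.iterrows()
    ]

    vt = pd.read_csv(path / "vitals.csv", float_precision="round_trip")
    vitals = VitalsTrace(
        vt["time_s"].to_numpy(),
        vt["sao2"].to_numpy(),
        vt["map_mmhg"].to_numpy(),
        vt["hr_bpm"].to_numpy(),
    )

    masks = []
    if (path / "masks.csv").exists():
        mdf = pd.read_csv(path / "masks.csv", float_precision="round_trip")
        for source, sub in mdf.groupby("source"):
            masks.append(
                ArtifactMask(
                    [(float(a), float(b)) for a, b in zip(sub["t_start_s"], sub["t_end_s"])],
                    source=str(source),
                )
            )

    dtofs, g2s, irfs = [], [], {}
    with h5py.File(path / "optical.h5", "r") as h5:
        if "trs" not in h5:
            raise BundleError(f"optical.h5 in {path} lacks the /trs group")
        for loc in h5["trs"]:
            grp = h5[f"trs/{loc}"]
            wavelengths = grp["wavelengths"][()]
            ts = grp["timestamps"][()]
            counts = grp["counts"][()]
            bin_width = float(grp["bin_width_ps"][()])
            for wi, w in enumerate(wavelengths):
                irfs[float(w)] = IRFRecord(bin_width, grp["irf"][wi], float(w))
                for ti, t in enumerate(ts):
                    dtofs.append(
                        DTOFRecord(float(t), float(w), bin_width, counts[wi, ti], loc)
                    )
        if "dcs" in h5:
            for loc in h5["dcs"]:
                grp = h5[f"dcs/{loc}"]
                tau = grp["tau"][()]
                cr = grp["count_rate_khz"][()]
                for ti, t in enumerate(grp["timestamps"][()]):
                    g2s.append(
                        G2Record(float(t), tau, grp["g2"][ti], float(cr[ti]), loc)
                    )

    instrument = InstrumentSpec(
        trs_rho=float(meta["trs_rho_mm"]),
        dcs_rho=float(meta["dcs_rho_mm"]),
        n_tissue=float(meta.get("n_tissue", 1.4)),
        n_outside=float(meta.get("n_outside", 1.0)),
        wavelengths=tuple(float(w) for w in meta.get("wavelengths_nm", (690.0, 830.0))),
    )
    return RawSessionBundle(
        subject_id=str(meta["subject_id"]),
        dtofs=dtofs,
        irfs=irfs,
        g2s=g2s,
        vitals=vitals,
        bloodgas=bloodgas,
        events=events,
        masks=masks,
        instrument=instrument,
        seed=int(meta.get("seed", 0)),
    )


def write_processed(session: SubjectSession, qc: pd.DataFrame, path) -> None:
    """Persist a processed session: tidy traces, blood gases, QC, metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for (loc, var), tr in sorted(session.traces.items()):
        for t, v in zip(tr.timestamps, tr.values):
            rows.append(
                {"timestamp": t, "location": loc, "variable": var, "value": v}
            )
    _write_csv(pd.DataFrame(rows), path / "traces.csv")
    _write_csv(
        pd.DataFrame(
            [
                {
                    "time_s": s.time,
                    "period": s.period,
                    "hgb_gdl": s.hgb,
                    "hct_pct": s.hct,
                    "paco2_mmhg": s.paco2,
                }
                for s in session.bloodgas
            ]
        ),
        path / "bloodgas.csv",
    )
    qc.to_csv(path / "qc.csv", index=False)
    meta = {
        "subject_id": session.subject_id,
        "events": {
            k: (list(map(float, v)) if isinstance(v, (list, tuple)) else float(v))
            for k, v in session.events.items()
        },
        "meta": {k: v for k, v in session.meta.items() if k != "config"},
        "config": session.meta.get("config", {}),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_processed(path) -> tuple[SubjectSession, pd.DataFrame]:
    """Rebuild a processed session (traces, blood gases, events) from disk."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    df = pd.read_csv(path / "traces.csv", float_precision="round_trip")
    traces = {}
    for (loc, var), sub in df.groupby(["location", "variable"]):
        sub = sub.sort_values("timestamp")
        traces[(loc, var)] = HemoTrace(
            loc, var, sub["timestamp"].to_numpy(), sub["value"].to_numpy()
        )
    bg = pd.read_csv(path / "bloodgas.csv", float_precision="round_trip")
    bloodgas = [
        BloodGasSample(
            time=float(r["time_s"]),
            hgb=float(r["hgb_gdl"]),
            hct=float(r["hct_pct"]),
            paco2=float(r["paco2_mmhg"]),
            period=str(r["period"]),
        )
        for _, r in bg.iterrows()
    ]
    qc = pd.read_csv(path / "qc.csv") if (path / "qc.csv").exists() else pd.DataFrame()
    session = SubjectSession(
        subject_id=str(meta["subject_id"]),
        traces=traces,
        vitals=None,
        bloodgas=bloodgas,
        events=meta["events"],
        meta=meta.get("meta", {}),
    )
    return session, qc
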