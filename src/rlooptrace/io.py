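"""Readers and writers for the pipeline's on-disk formats.

* Trajectories: tidy event TSV (one-way export) and an HDF5 archival
  container that round-trips full :class:`StateTrajectory` objects.
* Traces: cohort HDF5 (round-trip) and per-molecule wide TSV (round-trip).
* Calls: TSV table, one row per molecule.
* Summaries: JSON.
* Movies: one multi-frame TIFF per channel plus a JSON sidecar of
  ground-truth spot positions.

HDF5 layouts are documented in the README.  Real data exported in the
same tabular/TIFF shapes is ingestible through the same readers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .params import KineticParams
from .photophysics import CHANNELS, Trace
from .simulate import StateTrajectory
from .templates import TemplateSpec, build_template

__all__ = [
    "trajectories_to_events_frame",
    "write_events_tsv",
    "save_trajectories_h5",
    "load_trajectories_h5",
    "save_traces_h5",
    "load_traces_h5",
    "trace_to_tsv",
    "trace_from_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_summary_json",
    "save_movie",
    "load_movie",
]


def _template_to_dict(t: TemplateSpec) -> dict:
    d = dataclasses.asdict(t)
    d["dye_labels"] = [[l["dye"], l["strand"], l["position"]]
                       for l in d["dye_labels"]]
    d["promoter_window"] = list(d["promoter_window"])
    return d


def _params_to_dict(p: KineticParams) -> dict:
    d = dataclasses.asdict(p)
    d["p_branch"] = list(d["p_branch"])
    return d


# ---------------------------------------------------------------------------
def trajectories_to_events_frame(trajs: list[StateTrajectory]) -> pd.DataFrame:
    """Tidy event table: molecule_id, t, event_kind, payload (JSON)."""
    rows = []
    for tr in trajs:
        for t, kind, payload in tr.events:
            rows.append(
                dict(molecule_id=tr.molecule_id, t=t, event_kind=kind,
                     payload=json.dumps(payload, sort_keys=True))
            )
    return pd.DataFrame(rows, columns=["molecule_id", "t", "event_kind",
                                       "payload"])


def write_events_tsv(path, trajs: list[StateTrajectory]) -> None:
    trajectories_to_events_frame(trajs).to_csv(path, sep="\t", index=False)


_TRAJ_FIELDS = (
    "molecule_id", "seed", "active", "branch", "internal", "t_arrive",
    "t_internal", "internal_pos", "t_rloop_init", "rloop_downstream",
    "t_rna_loss", "t_digested", "t_hybrid_end",
)


def save_trajectories_h5(path, trajs: list[StateTrajectory]) -> None:
    """Archive trajectories: /molecules/<i> groups with landmark attrs,
    binding-time datasets and shared template/params JSON at the root."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "rlooptrace-trajectories-v1"
        f.attrs["template"] = json.dumps(_template_to_dict(trajs[0].template))
        f.attrs["params"] = json.dumps(_params_to_dict(trajs[0].params))
        g = f.create_group("molecules")
        for i, tr in enumerate(trajs):
            gi = g.create_group(str(i))
            state = {k: getattr(tr, k) for k in _TRAJ_FIELDS}
            state["reinit_events"] = list(tr.reinit_events)
            gi.attrs["state"] = json.dumps(state, default=_json_default)
            gi.create_dataset("ab_times", data=np.asarray(tr.ab_times))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {o!r}")


def load_trajectories_h5(path) -> list[StateTrajectory]:
    with h5py.File(path, "r") as f:
        tpl_doc = json.loads(f.attrs["template"])
        template = build_template(
            {**tpl_doc,
             "dye_labels": [tuple(l) for l in tpl_doc["dye_labels"]]}
        )
        pd_doc = json.loads(f.attrs["params"])
        pd_doc["p_branch"] = tuple(pd_doc["p_branch"])
        params = KineticParams(**pd_doc)
        out = []
        g = f["molecules"]
        for key in sorted(g, key=int):
            gi = g[key]
            state = json.loads(gi.attrs["state"])
            reinit = tuple((float(t), str(k))
                           for t, k in state.pop("reinit_events", []))
            if state.get("t_hybrid_end") is None:
                state["t_hybrid_end"] = np.inf
            out.append(
                StateTrajectory(
                    template=template, params=params,
                    ab_times=np.asarray(gi["ab_times"][()]),
                    reinit_events=reinit, **state,
                )
            )
    return out


# ---------------------------------------------------------------------------
def save_traces_h5(path, traces: list[Trace], attrs: dict | None = None) -> None:
    """Cohort trace container: /t (frame starts), /channels/<name> as
    (n_molecules, n_frames) arrays, /molecule_id; scalar metadata in root
    attrs.  Ground-truth links are not archived."""
    if not traces:
        raise ValueError("no traces to save")
    n = traces[0].n_frames
    if any(tr.n_frames != n for tr in traces):
        raise ValueError("traces must share one time axis")
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "rlooptrace-traces-v1"
        f.attrs["frame_dt"] = traces[0].frame_dt
        schemes = {tr.provenance.get("scheme") for tr in traces}
        if len(schemes) == 1 and None not in schemes:
            f.attrs["scheme"] = schemes.pop()
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        f.create_dataset("t", data=traces[0].t)
        f.create_dataset(
            "molecule_id", data=np.asarray([tr.molecule_id for tr in traces])
        )
        g = f.create_group("channels")
        for ch in CHANNELS:
            g.create_dataset(
                ch, data=np.stack([tr.channel(ch) for tr in traces])
            )


def load_traces_h5(path) -> list[Trace]:
    with h5py.File(path, "r") as f:
        t = f["t"][()]
        ids = f["molecule_id"][()]
        frame_dt = float(f.attrs["frame_dt"])
        scheme = f.attrs.get("scheme")
        chans = {ch: f["channels"][ch][()] for ch in CHANNELS}
    prov = {"source": str(path)}
    if scheme is not None:
        prov["scheme"] = str(scheme)
    return [
        Trace(
            molecule_id=int(ids[i]),
            frame_dt=frame_dt,
            t=t.copy(),
            channels={ch: chans[ch][i] for ch in CHANNELS},
            provenance=dict(prov),
        )
        for i in range(len(ids))
    ]


def trace_to_tsv(path, trace: Trace) -> None:
    """Wide per-molecule TSV: frame, t and the four channels."""
    df = pd.DataFrame({"frame": np.arange(trace.n_frames), "t": trace.t})
    for ch in CHANNELS:
        df[ch] = trace.channel(ch)
    df.to_csv(path, sep="\t", index=False)


def trace_from_tsv(path, frame_dt: float | None = None,
                   molecule_id: int = 0) -> Trace:
    df = pd.read_csv(path, sep="\t")
    t = df["t"].to_numpy(float)
    if frame_dt is None:
        frame_dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return Trace(
        molecule_id=molecule_id,
        frame_dt=frame_dt,
        t=t,
        channels={ch: df[ch].to_numpy(float) for ch in CHANNELS},
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------------------
def write_calls_tsv(path, calls: pd.DataFrame) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_json(path, summary) -> None:
    """Serialize a CohortSummary (or plain dict) to JSON."""
    if dataclasses.is_dataclass(summary):
        doc = dataclasses.asdict(summary)
        doc.pop("curves", None)
    else:
        doc = dict(summary)
    Path(path).write_text(json.dumps(doc, indent=2, default=_json_default))


# ---------------------------------------------------------------------------
def save_movie(outdir, stacks: dict[str, np.ndarray],
               spots: pd.DataFrame) -> None:
    """One multi-frame TIFF per channel plus spots.json ground truth."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch, stack in stacks.items():
        tifffile.imwrite(outdir / f"{ch}.tif", np.asarray(stack, np.float32))
    (outdir / "spots.json").write_text(
        json.dumps(spots.to_dict(orient="list"), indent=2)
    )


def load_movie(outdir) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    import tifffile

    outdir = Path(outdir)
    stacks = {
        ch: tifffile.imread(outdir / f"{ch}.tif") for ch in CHANNELS
        if (outdir / f"{ch}.tif").exists()
    }
    spots = pd.DataFrame(json.loads((outdir / "spots.json").read_text()))
    return stacks, spots
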