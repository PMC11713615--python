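"""On-disk formats: CSV matrices (human-diffable at culture scale), JSON
metadata sidecars, YAML run configs. Units are seconds and µm throughout.

Rasters are stored as 0/1 (a ``1`` marks activity) with the bin width in a
``# tau=<seconds>`` comment line; the in-memory convention is ±1 and the
0→−1 mapping is applied on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binarize import FluorescenceTraces, SpikeEvents
from .inference import Hyperparameters, InferenceResult, LatentPosteriors
from .model import EffectiveNetwork, SpikeRaster

__all__ = [
    "read_raster", "write_raster",
    "read_positions", "write_positions",
    "read_traces", "read_events", "write_events",
    "read_network", "write_network",
    "write_result", "read_result",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, raster: SpikeRaster) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# tau={raster.tau}\n")
        fh.write(",".join(raster.unit_ids) + "\n")
        zero_one = ((raster.states.T + 1) // 2).astype(int)  # bins x units
        np.savetxt(fh, zero_one, fmt="%d", delimiter=",")


def read_raster(path: str | Path) -> SpikeRaster:
    """Read a 0/1 raster CSV (rows = bins, columns = units) with its
    ``# tau=`` header; values other than 0/1 raise with their location."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if not text:
        raise ValueError(f"{path}: empty raster file")
    tau = None
    header_rows = 0
    for line in text:
        if line.startswith("#"):
            header_rows += 1
            if "tau=" in line:
                tau = float(line.split("tau=")[1].strip())
        else:
            break
    if tau is None:
        raise ValueError(f"{path}: missing '# tau=<seconds>' header")
    if header_rows >= len(text):
        raise ValueError(f"{path}: no data rows")
    unit_ids = [c.strip() for c in text[header_rows].split(",")]
    body = text[header_rows + 1:]
    if not body:
        raise ValueError(f"{path}: no data rows")
    states = np.empty((len(body), len(unit_ids)), dtype=np.int8)
    for r, line in enumerate(body):
        cells = line.split(",")
        if len(cells) != len(unit_ids):
            raise ValueError(f"{path}: row {r + 1} has {len(cells)} cells, "
                             f"expected {len(unit_ids)}")
        for c, cell in enumerate(cells):
            v = cell.strip()
            if v not in ("0", "1"):
                raise ValueError(f"{path}: non-binary value {v!r} at row "
                                 f"{r + 1}, column {unit_ids[c]!r}")
            states[r, c] = 1 if v == "1" else -1
    return SpikeRaster(states=states.T, tau=tau, unit_ids=unit_ids)


# ---------------------------------------------------------------------------
# positions, traces, events
# ---------------------------------------------------------------------------

def write_positions(path: str | Path, positions: np.ndarray,
                    unit_ids: list[str] | None = None,
                    stripe_id: np.ndarray | None = None) -> None:
    n = positions.shape[0]
    df = pd.DataFrame({
        "unit_id": unit_ids or [f"u{i}" for i in range(n)],
        "x_um": positions[:, 0], "y_um": positions[:, 1]})
    if stripe_id is not None:
        df["stripe_id"] = np.asarray(stripe_id, dtype=int)
    df.to_csv(path, index=False)


def read_positions(path: str | Path,
                   ) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Read unit coordinates (µm); returns (positions, unit_ids, stripe_id)."""
    df = pd.read_csv(path)
    for col in ("unit_id", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    ids = df["unit_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate unit_id")
    pos = df[["x_um", "y_um"]].to_numpy(dtype=float)
    stripe = df["stripe_id"].to_numpy(dtype=int) if "stripe_id" in df.columns else None
    return pos, ids, stripe


def read_traces(path: str | Path, frame_rate: float | None = None) -> FluorescenceTraces:
    """CSV traces: first column is time in seconds, one column per unit.
    HDF5 (.h5/.hdf5) files hold a (frames × units) dataset ``traces`` with a
    ``frame_rate`` attribute."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as fh:
            ds = fh["traces"]
            rate = float(ds.attrs.get("frame_rate", frame_rate or 0))
            ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in fh.get("unit_ids", [])] or None
            values = ds[()]
        if rate <= 0:
            raise ValueError("frame_rate attribute missing")
        return FluorescenceTraces(values=values, frame_rate=rate,
                                  unit_ids=ids or [])
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 frames")
    rate = frame_rate or 1.0 / float(np.median(np.diff(t)))
    return FluorescenceTraces(values=df.iloc[:, 1:].to_numpy(dtype=float),
                              frame_rate=rate,
                              unit_ids=[str(c) for c in df.columns[1:]])


def write_events(path: str | Path, events: SpikeEvents) -> None:
    rows = [(events.unit_ids[u], t) for u in range(events.n_units)
            for t in events.times[u]]
    df = pd.DataFrame(rows, columns=["unit", "time_s"])
    with Path(path).open("w") as fh:
        fh.write(f"# duration={events.duration}\n")
        fh.write(f"# units={','.join(events.unit_ids)}\n")
        df.to_csv(fh, index=False)


def read_events(path: str | Path) -> SpikeEvents:
    path = Path(path)
    duration = None
    unit_ids: list[str] | None = None
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        if "duration=" in line:
            duration = float(line.split("duration=")[1])
        elif "units=" in line:
            unit_ids = line.split("units=")[1].strip().split(",")
        n_header += 1
    import io as _io
    df = pd.read_csv(_io.StringIO("\n".join(lines[n_header:])))
    if duration is None:
        raise ValueError(f"{path}: missing '# duration=' header")
    if unit_ids is None:
        unit_ids = sorted(df["unit"].astype(str).unique())
    times = [np.sort(df.loc[df["unit"].astype(str) == u, "time_s"].to_numpy(dtype=float))
             for u in unit_ids]
    return SpikeEvents(times=times, duration=duration, unit_ids=unit_ids)


# ---------------------------------------------------------------------------
# networks and inference results
# ---------------------------------------------------------------------------

def write_network(outdir: str | Path, net: EffectiveNetwork,
                  tau: float | None = None, meta: dict | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "J.csv", net.J, delimiter=",")
    np.savetxt(outdir / "H.csv", net.H, delimiter=",")
    sidecar = {"unit_ids": net.unit_ids, "tau": tau, **(meta or {})}
    (outdir / "network.json").write_text(json.dumps(sidecar, indent=1))


def read_network(outdir: str | Path) -> tuple[EffectiveNetwork, dict]:
    outdir = Path(outdir)
    J = np.loadtxt(outdir / "J.csv", delimiter=",")
    H = np.loadtxt(outdir / "H.csv", delimiter=",")
    meta = json.loads((outdir / "network.json").read_text())
    net = EffectiveNetwork(J=np.atleast_2d(J), H=np.atleast_1d(H),
                           unit_ids=meta.get("unit_ids") or [])
    return net, meta


def write_result(outdir: str | Path, result: InferenceResult,
                 tau: float | None = None, meta: dict | None = None) -> None:
    """Inference-result directory: J.csv, H.csv, pz.csv, pphi.csv, rho.json,
    trace.csv plus a metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(outdir, result.net, tau=tau,
                  meta={"method": result.method,
                        "converged": bool(result.converged), **(meta or {})})
    np.savetxt(outdir / "pz.csv", result.latents.pz, delimiter=",")
    np.savetxt(outdir / "pphi.csv", result.latents.pphi, delimiter=",")
    np.savetxt(outdir / "z_hat.csv", result.z_hat, fmt="%d", delimiter=",")
    np.savetxt(outdir / "phi_hat.csv", result.phi_hat, fmt="%d", delimiter=",")
    (outdir / "rho.json").write_text(json.dumps(result.rho.as_dict(), indent=1))
    np.savetxt(outdir / "trace.csv", np.asarray(result.trace), delimiter=",")


def read_result(outdir: str | Path) -> InferenceResult:
    outdir = Path(outdir)
    net, meta = read_network(outdir)
    pz = np.atleast_1d(np.loadtxt(outdir / "pz.csv", delimiter=","))
    pphi = np.atleast_2d(np.loadtxt(outdir / "pphi.csv", delimiter=","))
    z_hat = np.atleast_1d(np.loadtxt(outdir / "z_hat.csv", delimiter=",")).astype(int)
    phi_hat = np.atleast_2d(np.loadtxt(outdir / "phi_hat.csv", delimiter=",")).astype(int)
    rho = Hyperparameters(**json.loads((outdir / "rho.json").read_text()))
    trace = np.atleast_1d(np.loadtxt(outdir / "trace.csv", delimiter=",")).tolist()
    return InferenceResult(net=net, latents=LatentPosteriors(pz=pz, pphi=pphi),
                           rho=rho, z_hat=z_hat, phi_hat=phi_hat, trace=trace,
                           converged=bool(meta.get("converged", True)),
                           method=str(meta.get("method", "gml")))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved run parameters; written next to every output directory so a
    deterministic stage can be reproduced bit-identically."""

    seed: int = 0
    subcommand: str = ""
    params: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
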