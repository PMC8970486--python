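"""Rotor and activation-map analysis of spatiotemporal voltage data.

Transmembrane-voltage movies are turned into phase movies (15 Hz low-pass,
DC removal, Hilbert transform), phase singularities (PS) are detected by
the winding-number rule — a closed contour integral of the phase equal to
+/- 2 pi marks a rotor core — and tracked over time under a 2 mm/ms
mobility gate. Rotors sustained for at least 100 ms define the
rotor-duration statistic that correlates with AF inducibility. The module
also computes local activation time (first upward -30 mV crossing),
repolarization time (first downward -70 mV crossing) and APD maps, and
brackets the effective refractory period from conduction-block outcomes
over a cycle-length grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "VoltageField",
    "PhaseField",
    "PsTrack",
    "ActivationMap",
    "ErpBracket",
    "read_voltage_field",
    "write_voltage_field",
    "phase_from_vm",
    "detect_ps",
    "track_ps",
    "rotor_duration",
    "activation_repolarization",
    "estimate_erp",
]


@dataclass(frozen=True)
class VoltageField:
    """Node x time transmembrane voltages in mV with geometry.

    Either ``grid_shape`` (regular ny x nx grid with ``spacing_mm``) or
    ``faces`` (triangle list into ``node_xyz``) describes the geometry.
    """

    vm: np.ndarray  # (N, T) mV
    fs: float  # Hz
    node_xyz: np.ndarray | None = None  # (N, 3) mm
    faces: np.ndarray | None = None  # (F, 3) int
    grid_shape: tuple | None = None  # (ny, nx)
    spacing_mm: float = 1.0

    def __post_init__(self):
        vm = np.asarray(self.vm, dtype=float)
        object.__setattr__(self, "vm", vm)
        if vm.ndim != 2:
            raise ValueError("vm must be (nodes, time)")
        if not np.all(np.isfinite(vm)):
            raise ValueError("vm must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.grid_shape is not None:
            ny, nx = self.grid_shape
            if ny * nx != vm.shape[0]:
                raise ValueError("grid_shape does not match node count")
        elif self.faces is not None:
            faces = np.asarray(self.faces, dtype=int)
            object.__setattr__(self, "faces", faces)
            if faces.min() < 0 or faces.max() >= vm.shape[0]:
                raise ValueError("faces index nodes out of range")
            if self.node_xyz is None:
                raise ValueError("triangulated field needs node_xyz")
        else:
            raise ValueError("provide grid_shape or faces")


@dataclass(frozen=True)
class PhaseField:
    """Node x time phase in (-pi, pi] with the source field's geometry."""

    phase: np.ndarray  # (N, T)
    fs: float
    mask: np.ndarray  # (N,) True where phase is defined
    node_xyz: np.ndarray | None = None
    faces: np.ndarray | None = None
    grid_shape: tuple | None = None
    spacing_mm: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.phase.shape[1]


@dataclass(frozen=True)
class PsTrack:
    """A tracked phase-singularity trajectory."""

    frames: np.ndarray  # frame indices
    positions: np.ndarray  # (n, 2 or 3) mm
    chirality: int  # +1 or -1
    fs: float

    @property
    def duration_ms(self) -> float:
        return self.frames.size / self.fs * 1000.0

    @property
    def start_ms(self) -> float:
        return self.frames[0] / self.fs * 1000.0

    @property
    def end_ms(self) -> float:
        """End of the half-open [start, end) lifetime interval."""
        return (self.frames[-1] + 1) / self.fs * 1000.0

    def sustained(self, min_ms: float = 100.0) -> bool:
        return self.duration_ms >= min_ms


@dataclass(frozen=True)
class ActivationMap:
    """Per-node activation/repolarization times (ms since stimulus), NaN
    where no crossing was found; apd = repol - lat."""

    lat_ms: np.ndarray
    repol_ms: np.ndarray
    apd_ms: np.ndarray
    reference_t0: float


@dataclass(frozen=True)
class ErpBracket:
    """ERP bounds: conduction blocked at ``lower_cl_ms``, conducted at
    ``upper_cl_ms``; -inf / +inf sentinels at the grid edges."""

    lower_cl_ms: float
    upper_cl_ms: float

    def __post_init__(self):
        if not self.lower_cl_ms < self.upper_cl_ms:
            raise ValueError("ERP bracket requires lower < upper")


# ---------------------------------------------------------------------------
# HDF5 I/O for voltage fields (node x time movies get large quickly)


def write_voltage_field(vf: VoltageField, path) -> None:
    """Store a voltage field as HDF5 (vm, fs, geometry datasets)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("vm", data=vf.vm, compression="gzip")
        f.attrs["fs"] = vf.fs
        f.attrs["spacing_mm"] = vf.spacing_mm
        if vf.grid_shape is not None:
            f.attrs["grid_shape"] = vf.grid_shape
        if vf.node_xyz is not None:
            f.create_dataset("node_xyz", data=vf.node_xyz)
        if vf.faces is not None:
            f.create_dataset("faces", data=vf.faces)


def read_voltage_field(path) -> VoltageField:
    """Load a voltage field written by :func:`write_voltage_field`."""
    import h5py

    with h5py.File(path, "r") as f:
        grid_shape = f.attrs.get("grid_shape")
        return VoltageField(
            vm=f["vm"][...],
            fs=float(f.attrs["fs"]),
            spacing_mm=float(f.attrs.get("spacing_mm", 1.0)),
            grid_shape=tuple(int(v) for v in grid_shape)
            if grid_shape is not None else None,
            node_xyz=f["node_xyz"][...] if "node_xyz" in f else None,
            faces=f["faces"][...] if "faces" in f else None,
        )


# ---------------------------------------------------------------------------
# Phase computation


def phase_from_vm(vf: VoltageField, lp_hz: float = 15.0, order: int = 4) -> PhaseField:
    """Phase movie: low-pass filter, remove DC, take the analytic-signal angle.

    Constant node traces have undefined phase and are masked out.
    """
    if vf.fs <= 2 * lp_hz:
        raise ValueError(f"fs = {vf.fs} too low for a {lp_hz} Hz low-pass")
    vm = vf.vm
    mask = vm.std(axis=1) > 0
    sos = sps.butter(order, lp_hz, btype="lowpass", fs=vf.fs, output="sos")
    filt = sps.sosfiltfilt(sos, vm, axis=1)
    filt = filt - filt.mean(axis=1, keepdims=True)
    analytic = sps.hilbert(filt, axis=1)
    phase = np.angle(analytic)
    phase[~mask] = 0.0
    return PhaseField(
        phase=phase,
        fs=vf.fs,
        mask=mask,
        node_xyz=vf.node_xyz,
        faces=vf.faces,
        grid_shape=vf.grid_shape,
        spacing_mm=vf.spacing_mm,
    )


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * d))


def detect_ps(
    pf: PhaseField, t: int, tol: float = np.pi / 4
) -> list[tuple[np.ndarray, int]]:
    """Phase singularities in one frame by the winding-number criterion.

    Each elementary closed loop — a grid plaquette on regular grids, a
    triangle on meshes — is traversed and its wrapped phase differences
    summed; a total within ``tol`` of +/- 2 pi marks a PS at the loop
    centroid with the sign of the winding as chirality. Loops touching a
    masked node are skipped.
    """
    ph = pf.phase[:, t]
    out: list[tuple[np.ndarray, int]] = []
    if pf.grid_shape is not None:
        ny, nx = pf.grid_shape
        P = ph.reshape(ny, nx)
        M = pf.mask.reshape(ny, nx)
        # corners of every plaquette, counter-clockwise
        a = P[:-1, :-1]
        b = P[:-1, 1:]
        c = P[1:, 1:]
        d = P[1:, :-1]
        winding = _wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)
        ok = M[:-1, :-1] & M[:-1, 1:] & M[1:, 1:] & M[1:, :-1]
        hit = ok & (np.abs(np.abs(winding) - 2 * np.pi) < tol)
        ys, xs = np.nonzero(hit)
        h = pf.spacing_mm
        for y, x in zip(ys, xs):
            pos = np.array([(x + 0.5) * h, (y + 0.5) * h])
            out.append((pos, int(np.sign(winding[y, x]))))
    else:
        tri = pf.faces
        pa, pb, pc = ph[tri[:, 0]], ph[tri[:, 1]], ph[tri[:, 2]]
        winding = _wrap(pb - pa) + _wrap(pc - pb) + _wrap(pa - pc)
        ok = pf.mask[tri].all(axis=1)
        hit = ok & (np.abs(np.abs(winding) - 2 * np.pi) < tol)
        for f in np.nonzero(hit)[0]:
            pos = pf.node_xyz[tri[f]].mean(axis=0)
            out.append((pos, int(np.sign(winding[f]))))
    return out


# ---------------------------------------------------------------------------
# Tracking


def track_ps(
    ps_per_frame,
    fs: float,
    max_speed_mm_per_ms: float = 2.0,
) -> list[PsTrack]:
    """Link per-frame PS detections into trajectories.

    Greedy nearest-neighbor assignment between consecutive frames: pairs
    of equal chirality are matched in order of increasing displacement,
    subject to the mobility gate ``max_speed * frame interval``. Unmatched
    detections open new tracks; tracks end when unmatched.
    """
    dt_ms = 1000.0 / fs
    gate = max_speed_mm_per_ms * dt_ms
    open_tracks: list[dict] = []
    done: list[PsTrack] = []

    for fi, dets in enumerate(ps_per_frame):
        dets = list(dets)
        matched_det = set()
        matched_trk = set()
        if open_tracks and dets:
            pairs = []
            for ti, trk in enumerate(open_tracks):
                for di, (pos, chir) in enumerate(dets):
                    if chir != trk["chirality"]:
                        continue
                    dist = float(np.linalg.norm(np.asarray(pos) - trk["last_pos"]))
                    if dist <= gate:
                        pairs.append((dist, ti, di))
            for _, ti, di in sorted(pairs):
                if ti in matched_trk or di in matched_det:
                    continue
                trk = open_tracks[ti]
                pos, _ = dets[di]
                trk["frames"].append(fi)
                trk["positions"].append(np.asarray(pos, dtype=float))
                trk["last_pos"] = np.asarray(pos, dtype=float)
                matched_trk.add(ti)
                matched_det.add(di)
        # close unmatched tracks
        still_open = []
        for ti, trk in enumerate(open_tracks):
            if ti in matched_trk:
                still_open.append(trk)
            else:
                done.append(_finalize(trk, fs))
        open_tracks = still_open
        # open new tracks for unmatched detections
        for di, (pos, chir) in enumerate(dets):
            if di not in matched_det:
                p = np.asarray(pos, dtype=float)
                open_tracks.append(
                    {"frames": [fi], "positions": [p], "last_pos": p,
                     "chirality": int(chir)}
                )
    done.extend(_finalize(t, fs) for t in open_tracks)
    done.sort(key=lambda t: (t.frames[0], t.chirality))
    return done


def _finalize(trk: dict, fs: float) -> PsTrack:
    return PsTrack(
        frames=np.asarray(trk["frames"], dtype=int),
        positions=np.asarray(trk["positions"], dtype=float),
        chirality=trk["chirality"],
        fs=fs,
    )


def rotor_duration(tracks, min_ms: float = 100.0) -> float:
    """Total time (ms) during which at least one sustained rotor exists.

    Tracks shorter than ``min_ms`` are discarded; the measure of the union
    of the surviving tracks' lifetime intervals is returned.
    """
    ivals = sorted(
        (t.start_ms, t.end_ms) for t in tracks if t.duration_ms >= min_ms
    )
    total = 0.0
    cur_a = cur_b = None
    for a, b in ivals:
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


# ---------------------------------------------------------------------------
# Activation / repolarization maps and ERP


def _first_crossing(
    x: np.ndarray, thr: float, upward: bool, start: int
) -> float:
    """Index (fractional, linearly interpolated) of the first threshold
    crossing at or after ``start``; NaN if none."""
    if upward:
        hit = (x[start:-1] < thr) & (x[start + 1 :] >= thr)
    else:
        hit = (x[start:-1] > thr) & (x[start + 1 :] <= thr)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return float("nan")
    i = start + int(idx[0])
    frac = (thr - x[i]) / (x[i + 1] - x[i])
    return i + frac


def activation_repolarization(
    vf: VoltageField,
    t0: float = 0.0,
    depol_mv: float = -30.0,
    repol_mv: float = -70.0,
) -> ActivationMap:
    """Local activation, repolarization and APD per node.

    Activation is the first upward crossing of ``depol_mv`` after the
    stimulus time ``t0`` (ms); repolarization is the first downward
    crossing of ``repol_mv`` after activation. Crossing times are linearly
    interpolated between samples and reported in ms since ``t0``. Nodes
    without the respective crossing get NaN.
    """
    fs = vf.fs
    start = max(int(np.ceil(t0 * fs / 1000.0)), 0)
    N = vf.vm.shape[0]
    lat = np.full(N, np.nan)
    repol = np.full(N, np.nan)
    for n in range(N):
        x = vf.vm[n]
        a = _first_crossing(x, depol_mv, upward=True, start=start)
        if np.isnan(a):
            continue
        lat[n] = a / fs * 1000.0 - t0
        r = _first_crossing(x, repol_mv, upward=False, start=int(np.ceil(a)))
        if not np.isnan(r):
            repol[n] = r / fs * 1000.0 - t0
    return ActivationMap(
        lat_ms=lat, repol_ms=repol, apd_ms=repol - lat, reference_t0=t0
    )


def estimate_erp(block_by_cl: dict) -> ErpBracket:
    """Bracket the effective refractory period from pacing outcomes.

    ``block_by_cl`` maps tested cycle lengths (ms) to True (complete
    conduction block) or False (conducted). The ERP lies between the
    largest blocked CL and the smallest conducted CL above it; sentinels
    -inf / +inf are used when every CL conducted or blocked.
    """
    if not block_by_cl:
        raise ValueError("empty block/conduct map")
    cls_sorted = sorted(block_by_cl)
    blocked = [c for c in cls_sorted if block_by_cl[c]]
    if not blocked:
        return ErpBracket(lower_cl_ms=-np.inf, upper_cl_ms=cls_sorted[0])
    lower = max(blocked)
    conducted_above = [c for c in cls_sorted if not block_by_cl[c] and c > lower]
    if not conducted_above:
        return ErpBracket(lower_cl_ms=lower, upper_cl_ms=np.inf)
    # non-monotone responses: conducted CLs below the largest blocked CL
    if any(not block_by_cl[c] and c < lower for c in cls_sorted):
        warnings.warn(
            "non-monotone conduction outcomes; bracketing with the largest "
            "blocked CL and the smallest conducted CL above it",
            stacklevel=2,
        )
    return ErpBracket(lower_cl_ms=lower, upper_cl_ms=min(conducted_above))
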