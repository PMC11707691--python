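"""Run/stream plumbing: in-memory message streams with consumer groups,
HDF5 batch files with a virtual master, text stream output and the
end-to-end processing pipeline.

The network broker of a production deployment is out of scope here; the
:class:`RunStream` reproduces its delivery contract in-process — within one
consumer group each message is delivered to exactly one consumer, distinct
groups each observe every message in order — so the pipeline and its
parallel semantics are testable hermetically.
"""

from __future__ import annotations

import io
import math
import threading
from dataclasses import dataclass, field
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path

import h5py
import numpy as np

from . import asdf as asdf_mod
from .geometry import DetectorGeometry, MaskSpec, build_static_mask
from .lattice import UnitCell, check_cell
from .peaks import Peak, PeakSearchOptions, build_annulus_map, peakfinder8_search, radial_stats
from .predict import IntegrationOptions, Reflection, classify_hit, integrate, predict_reflections
from .profile import Profiler

__all__ = [
    "TIMEOUT",
    "END_OF_STREAM",
    "Message",
    "RunStream",
    "write_batched_frames",
    "read_master_frames",
    "write_stream_chunk",
    "parse_stream",
    "PipelineOptions",
    "PipelineResult",
    "run_pipeline",
]


class _Signal:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return f"<{self._name}>"


#: returned by next_message when no message arrived within the timeout
TIMEOUT = _Signal("timeout")
#: returned when the stream is closed and fully consumed by the group
END_OF_STREAM = _Signal("end-of-stream")


@dataclass
class Message:
    frame_id: int
    data: np.ndarray
    metadata: dict = field(default_factory=dict)


class RunStream:
    """One acquisition run as an ordered in-memory message stream.

    Messages are retained until every registered consumer group has passed
    them, after which they are evicted; ``cache_size`` (messages) bounds the
    number of live messages by blocking the producer.
    """

    def __init__(self, name: str, cache_size: int | None = None):
        self.name = name
        self.cache_size = cache_size
        self._messages: dict[int, Message] = {}
        self._next_index = 0
        self._cursors: dict[str, int] = {}
        self._closed = False
        self._cond = threading.Condition()

    def register_group(self, group: str) -> None:
        with self._cond:
            if group not in self._cursors:
                if self._messages and min(self._messages) > 0:
                    raise RuntimeError("cannot register a group after eviction began")
                self._cursors[group] = 0

    def produce(self, frame_id: int, data, metadata: dict | None = None) -> None:
        with self._cond:
            if self._closed:
                raise RuntimeError("stream is closed")
            while self.cache_size is not None and len(self._messages) >= self.cache_size:
                self._cond.wait()
            self._messages[self._next_index] = Message(frame_id, data, metadata or {})
            self._next_index += 1
            self._cond.notify_all()

    def close(self) -> None:
        with self._cond:
            self._closed = True
            self._cond.notify_all()

    @property
    def live_messages(self) -> int:
        with self._cond:
            return len(self._messages)

    def _evict(self) -> None:
        # caller holds the lock
        if not self._cursors:
            return
        low = min(self._cursors.values())
        for i in [i for i in self._messages if i < low]:
            del self._messages[i]
        self._cond.notify_all()

    def next_message(self, group: str, timeout: float = 3.0):
        """Next undelivered message for ``group``.

        Blocks up to ``timeout`` seconds; a timeout is a distinguishable
        result (:data:`TIMEOUT`), not an error, matching the polling
        behaviour of a streaming consumer API.
        """
        import time as _time

        with self._cond:
            if group not in self._cursors:
                raise KeyError(f"consumer group {group!r} not registered")
            end_time = _time.monotonic() + timeout
            while True:
                cur = self._cursors[group]
                if cur < self._next_index:
                    msg = self._messages[cur]
                    self._cursors[group] = cur + 1
                    self._evict()
                    return msg
                if self._closed:
                    return END_OF_STREAM
                remaining = end_time - _time.monotonic()
                if remaining <= 0:
                    return TIMEOUT
                self._cond.wait(remaining)


# ---------------------------------------------------------------------------
# HDF5 batch files with a virtual master


def write_batched_frames(
    frames,
    out_dir,
    batch_size: int = 1000,
    dataset: str = "data",
    master_name: str = "master.h5",
) -> tuple[Path, list[Path]]:
    """Write frames into batch files and a virtual master.

    Frames are grouped into ``batch_size`` per file; the master file exposes
    the whole run as a single logical stack via HDF5 virtual datasets, so
    the data can be accessed as if it were one file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    shape = frames[0].shape
    dtype = frames[0].dtype
    for f in frames:
        if f.shape != shape or f.dtype != dtype:
            raise ValueError("frame shape/dtype changed mid-run")
    n = len(frames)
    n_files = math.ceil(n / batch_size)
    batch_paths = []
    for b in range(n_files):
        chunk = frames[b * batch_size : (b + 1) * batch_size]
        p = out_dir / f"batch_{b:05d}.h5"
        with h5py.File(p, "w") as fh:
            fh.create_dataset(dataset, data=np.stack(chunk))
        batch_paths.append(p)
    layout = h5py.VirtualLayout(shape=(n, *shape), dtype=dtype)
    for b, p in enumerate(batch_paths):
        m = min(batch_size, n - b * batch_size)
        vs = h5py.VirtualSource(p.name, dataset, shape=(m, *shape))
        layout[b * batch_size : b * batch_size + m] = vs
    master = out_dir / master_name
    with h5py.File(master, "w") as fh:
        fh.create_virtual_dataset(dataset, layout)
    return master, batch_paths


def read_master_frames(master_path, dataset: str = "data") -> np.ndarray:
    with h5py.File(master_path, "r") as fh:
        return fh[dataset][...]


# ---------------------------------------------------------------------------
# text stream output (chunked per frame, full-precision round trip)

_BEGIN_CHUNK = "----- Begin chunk -----"
_END_CHUNK = "----- End chunk -----"
_BEGIN_CRYSTAL = "--- Begin crystal"
_END_CRYSTAL = "--- End crystal"


def write_stream_chunk(
    sink,
    frame_id: int,
    peaks: list[Peak],
    indexing_result=None,
    reflections: list[Reflection] | None = None,
) -> None:
    """Append one frame's results to a text stream.

    The chunk carries the peak table and, when the frame was indexed, the
    oriented cell (basis vectors and scalar parameters) plus the reflection
    table.  All floats are written with ``repr`` so parsing round-trips at
    full precision.
    """
    w = sink.write
    w(_BEGIN_CHUNK + "\n")
    w(f"frame_id = {frame_id}\n")
    w(f"num_peaks = {len(peaks)}\n")
    w("Peaks from peak search\n")
    w("fast slow intensity snr n_pixels\n")
    for p in peaks:
        w(
            f"{float(p.fast)!r} {float(p.slow)!r} {float(p.intensity)!r} "
            f"{float(p.snr)!r} {int(p.n_pixels)}\n"
        )
    w("End of peak list\n")
    if indexing_result is not None and getattr(indexing_result, "success", False):
        cell = indexing_result.cell
        w(_BEGIN_CRYSTAL + "\n")
        for label, vec in zip(("a_vec", "b_vec", "c_vec"), cell.basis.T):
            w(f"{label} = {float(vec[0])!r} {float(vec[1])!r} {float(vec[2])!r}\n")
        a, b, c, al, be, ga = cell.parameters
        w(f"cell_parameters = {a!r} {b!r} {c!r} {al!r} {be!r} {ga!r}\n")
        refl = reflections or []
        w(f"num_reflections = {len(refl)}\n")
        w("Reflections measured after indexing\n")
        w("h k l intensity sigma fast slow flag\n")
        for r in refl:
            w(
                f"{r.h} {r.k} {r.l} {float(r.intensity)!r} {float(r.sigma)!r} "
                f"{float(r.fast)!r} {float(r.slow)!r} {r.flag}\n"
            )
        w("End of reflections\n")
        w(_END_CRYSTAL + "\n")
    w(_END_CHUNK + "\n")


def parse_stream(source) -> list[dict]:
    """Parse text written by :func:`write_stream_chunk` into chunk dicts."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            lines = fh.read().splitlines()
    else:
        lines = source.read().splitlines()
    chunks = []
    i = 0
    while i < len(lines):
        if lines[i] != _BEGIN_CHUNK:
            i += 1
            continue
        i += 1
        chunk: dict = {"peaks": [], "cell_basis": None, "cell_parameters": None, "reflections": []}
        while i < len(lines) and lines[i] != _END_CHUNK:
            line = lines[i]
            if line.startswith("frame_id = "):
                chunk["frame_id"] = int(line.split("=")[1])
            elif line == "Peaks from peak search":
                i += 2  # skip header
                while lines[i] != "End of peak list":
                    f, s, inten, snr, npx = lines[i].split()
                    chunk["peaks"].append(
                        Peak(float(f), float(s), float(inten), float(snr), int(npx))
                    )
                    i += 1
            elif line.startswith("a_vec ="):
                basis = []
                for j in range(3):
                    basis.append([float(x) for x in lines[i + j].split("=")[1].split()])
                chunk["cell_basis"] = np.array(basis).T
                i += 2
            elif line.startswith("cell_parameters ="):
                chunk["cell_parameters"] = tuple(float(x) for x in line.split("=")[1].split())
            elif line == "Reflections measured after indexing":
                i += 2
                while lines[i] != "End of reflections":
                    h, k, l, inten, sig, f, s, flag = lines[i].split()
                    chunk["reflections"].append(
                        Reflection(
                            h=int(h),
                            k=int(k),
                            l=int(l),
                            q=np.zeros(3),
                            excitation_error=0.0,
                            fast=float(f),
                            slow=float(s),
                            intensity=float(inten),
                            sigma=float(sig),
                            flag=flag,
                        )
                    )
                    i += 1
            i += 1
        chunks.append(chunk)
        i += 1
    return chunks


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineOptions:
    peak_options: PeakSearchOptions = field(default_factory=PeakSearchOptions)
    asdf_options: asdf_mod.AsdfOptions = field(default_factory=asdf_mod.AsdfOptions)
    integration_options: IntegrationOptions = field(default_factory=IntegrationOptions)
    mask_spec: MaskSpec = field(default_factory=MaskSpec)
    min_peaks: int = 15
    #: retry indexing after deleting the weakest peaks; OFF by default, the
    #: real-time configuration (retrying costs much more time than it gains)
    retry: bool = False
    max_retries: int = 5
    retry_delete: int = 2
    seed: int = 0


@dataclass
class PipelineResult:
    summary: dict
    stream_text: str
    profiler: Profiler
    frame_results: dict


def _frame_seed(seed: int, frame_id: int) -> int:
    # one RNG per indexing call, derived from (global seed, frame id), so
    # results are independent of worker count and scheduling
    return int(np.random.SeedSequence((seed, frame_id)).generate_state(1)[0] % (2**31))


def _index_with_retry(peaks, geometry, reference, opts: PipelineOptions, frame_id: int):
    aopts = asdf_mod.AsdfOptions(**{**opts.asdf_options.__dict__})
    aopts.rng_seed = _frame_seed(opts.seed, frame_id)
    working = sorted(peaks, key=lambda p: -p.intensity)
    attempts = 1 + (opts.max_retries if opts.retry else 0)
    result = None
    for attempt in range(attempts):
        result = asdf_mod.asdf_index(working, geometry, reference, aopts)
        if result.success or len(working) - opts.retry_delete < 7:
            break
        working = working[: len(working) - opts.retry_delete]
    return result


def process_frame(
    frame_id: int,
    image: np.ndarray,
    geometry: DetectorGeometry,
    reference: UnitCell | None,
    options: PipelineOptions,
    annulus_map,
    static_mask: np.ndarray,
    profiler: Profiler,
) -> dict:
    """Mask, search, classify, index, predict, integrate one frame."""
    out: dict = {"frame_id": frame_id, "hit": False, "indexed": False}
    with profiler.record():
        with profiler.time_block("flag-values"):
            mask = static_mask | (image == options.mask_spec.sentinel_value)
        with profiler.time_block("peak-search"):
            with profiler.time_block("pf8-rstats"):
                stats = radial_stats(image, annulus_map, options.peak_options)
            with profiler.time_block("pf8-search"):
                peaks = peakfinder8_search(
                    image, annulus_map, stats, mask, options.peak_options
                )
        out["peaks"] = peaks
        out["hit"] = classify_hit(peaks, options.min_peaks)
        result = None
        reflections = None
        if out["hit"]:
            with profiler.time_block("asdf-search"):
                result = _index_with_retry(peaks, geometry, reference, options, frame_id)
            if result is not None and result.success and reference is not None:
                with profiler.time_block("prerefine-cell-check"):
                    match = check_cell(result.cell, reference)
                if not match.matched:
                    result = asdf_mod.IndexingResult(
                        False, None, result.n_candidates, "reference cell mismatch"
                    )
            if result is not None and result.success:
                with profiler.time_block("integration"):
                    predicted = predict_reflections(
                        result.cell, geometry, options.integration_options
                    )
                    reflections = integrate(
                        image, predicted, mask, options.integration_options
                    )
                out["indexed"] = True
        out["indexing_result"] = result
        out["reflections"] = reflections
    return out


def run_pipeline(
    source,
    geometry: DetectorGeometry,
    reference: UnitCell | None,
    options: PipelineOptions | None = None,
    n_workers: int = 1,
    stream_sink=None,
) -> PipelineResult:
    """Process a whole run.

    ``source`` is a :class:`RunStream` or an iterable of ``(frame_id,
    image)``.  Scientific output is independent of ``n_workers``: frames are
    processed with per-frame seeds and the stream chunks are written in
    frame-id order after the run.
    """
    options = options or PipelineOptions()
    if reference is not None and not isinstance(reference, UnitCell):
        raise TypeError("reference must be a UnitCell or None")
    static_mask = build_static_mask(options.mask_spec, geometry)
    annulus_map = build_annulus_map(geometry, static_mask)
    profiler = Profiler()
    prof_lock = threading.Lock()
    results: dict[int, dict] = {}

    class _WorkerProfiler:
        # one shared record list; completion order is arrival order
        def __init__(self):
            self._local = threading.local()

        def _prof(self):
            if not hasattr(self._local, "p"):
                self._local.p = Profiler()
            return self._local.p

        def record(self):
            return self._prof().record()

        def time_block(self, name):
            return self._prof().time_block(name)

        def harvest(self):
            p = self._prof()
            with prof_lock:
                for r in p.records:
                    r.completion_index = len(profiler.records)
                    profiler.records.append(r)
                p.records.clear()

    wp = _WorkerProfiler()

    def handle(frame_id, image):
        res = process_frame(
            frame_id, image, geometry, reference, options, annulus_map, static_mask, wp
        )
        wp.harvest()
        with prof_lock:
            results[frame_id] = res

    if isinstance(source, RunStream):
        group = "processing"
        source.register_group(group)

        def worker():
            while True:
                msg = source.next_message(group, timeout=3.0)
                if msg is END_OF_STREAM:
                    return
                if msg is TIMEOUT:
                    continue
                handle(msg.frame_id, msg.data)

        if n_workers == 1:
            worker()
        else:
            with ThreadPoolExecutor(max_workers=n_workers) as pool:
                futures = [pool.submit(worker) for _ in range(n_workers)]
                for f in futures:
                    f.result()
    else:
        items = list(source)
        if n_workers == 1:
            for frame_id, image in items:
                handle(frame_id, image)
        else:
            with ThreadPoolExecutor(max_workers=n_workers) as pool:
                futures = [pool.submit(handle, fid, img) for fid, img in items]
                for f in futures:
                    f.result()

    sink = stream_sink or io.StringIO()
    n_hits = n_indexed = 0
    for frame_id in sorted(results):
        res = results[frame_id]
        n_hits += res["hit"]
        n_indexed += res["indexed"]
        write_stream_chunk(
            sink, frame_id, res["peaks"], res.get("indexing_result"), res.get("reflections")
        )
    summary = {
        "n_frames": len(results),
        "n_hits": n_hits,
        "n_indexed": n_indexed,
        "hit_rate": n_hits / len(results) if results else 0.0,
        "indexing_rate": n_indexed / n_hits if n_hits else 0.0,
    }
    text = sink.getvalue() if isinstance(sink, io.StringIO) else ""
    return PipelineResult(
        summary=summary, stream_text=text, profiler=profiler, frame_results=results
    )
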