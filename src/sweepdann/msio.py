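"""ms-dialect text I/O and on-disk replicate stores.

Replicates are written in the standard Hudson ms dialect: one ``//`` record
per replicate followed by ``segsites:`` and a ``positions:`` line holding
site coordinates as fractions of the sequence length.  Positions are printed
with full double precision (rather than ms's historical 6 digits) so that a
write/read round trip is lossless; any ms-style file remains readable.
Files ending in ``.gz`` are compressed/decompressed transparently.

A replicate store is a directory holding ``replicates.ms`` plus an
``index.json`` sidecar recording label, domain, seed and parameters per
replicate, in file order.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
import os
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .sim import Demography, Epoch, HaplotypeSample, SimParams, SweepParams

__all__ = ["write_ms", "read_ms", "MsParseError", "ReplicateStore"]


class MsParseError(ValueError):
    """Malformed ms record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def _open_text(path_or_handle, mode: str):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    path = os.fspath(path_or_handle)
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t"), True
    return open(path, mode), True


def write_ms(samples: Union[HaplotypeSample, Iterable[HaplotypeSample]], sink) -> None:
    """Write replicates as ms-format text to a path or text handle."""
    if isinstance(samples, HaplotypeSample):
        samples = [samples]
    handle, owned = _open_text(sink, "w")
    try:
        first = True
        for s in samples:
            if not first:
                handle.write("\n")
            first = False
            handle.write("//\n")
            handle.write(f"segsites: {s.n_sites}\n")
            if s.n_sites:
                fracs = s.positions / s.L
                handle.write("positions: " + " ".join(repr(float(f)) for f in fracs) + "\n")
                for row in s.alleles:
                    handle.write("".join("1" if a else "0" for a in row) + "\n")
    finally:
        if owned:
            handle.close()


def read_ms(
    source,
    L: float = 1.0,
    label: str = "neutral",
    domain: str = "source",
    params: Optional[SimParams] = None,
) -> List[HaplotypeSample]:
    """Parse ms-format text into HaplotypeSamples.

    Positions are scaled back from fractions by ``L`` (taken from ``params``
    when given).  Label/domain apply to every replicate in the stream; per-
    replicate metadata lives in a store's index, not in the ms text itself.
    """
    if params is not None:
        L = params.L
    handle, owned = _open_text(source, "r")
    try:
        lines = handle.read().splitlines()
    finally:
        if owned:
            handle.close()

    samples: List[HaplotypeSample] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line != "//":
            if line == "" or not samples and not line.startswith(("segsites", "positions")):
                # tolerate ms command-line/seed header lines before the first record
                i += 1
                continue
            raise MsParseError(i + 1, f"expected '//', got {lines[i]!r}")
        i += 1
        if i >= n or not lines[i].startswith("segsites:"):
            raise MsParseError(i + 1, "expected 'segsites:' after '//'")
        try:
            segsites = int(lines[i].split(":", 1)[1])
        except ValueError as e:
            raise MsParseError(i + 1, f"bad segsites value: {e}") from e
        i += 1
        if segsites == 0:
            samples.append(
                HaplotypeSample(
                    positions=np.empty(0),
                    alleles=np.empty((0, 0), dtype=np.uint8),
                    label=label,
                    domain=domain,
                    params=params,
                )
            )
            continue
        if i >= n or not lines[i].startswith("positions:"):
            raise MsParseError(i + 1, "expected 'positions:' line")
        try:
            fracs = np.array([float(x) for x in lines[i].split()[1:]], dtype=np.float64)
        except ValueError as e:
            raise MsParseError(i + 1, f"bad position value: {e}") from e
        if fracs.size != segsites:
            raise MsParseError(i + 1, f"expected {segsites} positions, got {fracs.size}")
        i += 1
        rows = []
        while i < n and lines[i].strip() and lines[i].strip() != "//":
            hap = lines[i].strip()
            if len(hap) != segsites or set(hap) - {"0", "1"}:
                raise MsParseError(i + 1, "haplotype row must be 0/1 of segsites length")
            rows.append(np.frombuffer(hap.encode(), dtype=np.uint8) - ord("0"))
            i += 1
        if not rows:
            raise MsParseError(i, "replicate has no haplotype rows")
        samples.append(
            HaplotypeSample(
                positions=fracs * L,
                alleles=np.vstack(rows),
                label=label,
                domain=domain,
                params=params,
            )
        )
    return samples


# ----------------------------------------------------------------------


def _meta_to_dict(obj) -> Optional[dict]:
    if obj is None:
        return None
    d = dataclasses.asdict(obj)
    if isinstance(obj, Demography):
        d = {"epochs": [[e.duration, e.size] for e in obj.epochs]}
    return d


def _demography_from_dict(d: Optional[dict]) -> Optional[Demography]:
    if d is None:
        return None
    return Demography(epochs=tuple(Epoch(int(a), int(b)) for a, b in d["epochs"]))


class ReplicateStore:
    """Directory-backed collection of replicates with a JSON index.

    Layout: ``<root>/replicates.ms`` plus ``<root>/index.json`` whose
    ``replicates`` list carries ``{label, domain, seed}`` per replicate in
    file order, and whose top level records shared simulation parameters.
    """

    def __init__(self, root: Union[str, Path]):
        self.root = Path(root)

    @property
    def ms_path(self) -> Path:
        return self.root / "replicates.ms"

    @property
    def index_path(self) -> Path:
        return self.root / "index.json"

    def save(self, samples: Sequence[HaplotypeSample]) -> None:
        if not samples:
            raise ValueError("cannot save an empty replicate collection")
        self.root.mkdir(parents=True, exist_ok=True)
        write_ms(samples, self.ms_path)
        ref = samples[0]
        index = {
            "n_replicates": len(samples),
            "params": _meta_to_dict(ref.params),
            "demography": _meta_to_dict(ref.demography),
            "sweep_params": _meta_to_dict(ref.sweep),
            "replicates": [
                {"label": s.label, "domain": s.domain, "seed": s.seed,
                 "final_freq": s.final_freq}
                for s in samples
            ],
        }
        with open(self.index_path, "w") as fh:
            json.dump(index, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def load(self) -> List[HaplotypeSample]:
        with open(self.index_path) as fh:
            index = json.load(fh)
        params = SimParams(**index["params"]) if index.get("params") else None
        demography = _demography_from_dict(index.get("demography"))
        sweep = SweepParams(**index["sweep_params"]) if index.get("sweep_params") else None
        samples = read_ms(self.ms_path, params=params)
        meta = index["replicates"]
        if len(meta) != len(samples):
            raise ValueError(
                f"index lists {len(meta)} replicates but file holds {len(samples)}"
            )
        out = []
        for s, m in zip(samples, meta):
            out.append(
                HaplotypeSample(
                    positions=s.positions,
                    alleles=s.alleles,
                    label=m["label"],
                    domain=m["domain"],
                    params=params,
                    demography=demography,
                    sweep=sweep if m["label"] == "sweep" else None,
                    seed=m.get("seed"),
                    final_freq=m.get("final_freq"),
                )
            )
        return out
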