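"""Plain-text I/O: edge lists, hierarchy tables, sequence manifests.

Canonical formats, all tab-separated text:

* edge list — one ``source<TAB>target`` interaction per line; ``#`` comment
  lines and blank lines ignored; duplicates collapsed; self-loops dropped
  with a warning.
* hierarchy — header line ``# M=<int>`` then one ``node<TAB>level`` row per
  node.
* sequence manifest — a JSON document listing the member edge-list files in
  order plus the generator/mutation parameters and seeds that produced them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

from .graph import EvolvingSequence, Hierarchy, Network

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_hierarchy",
    "write_hierarchy",
    "write_sequence",
    "read_sequence",
]


def read_edge_list(path: str | Path) -> Network:
    """Parse a two-column tab-separated edge-list file."""
    path = Path(path)
    edges = []
    nodes = set()
    n_dupes = 0
    seen = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: malformed line {raw!r} "
                    "(expected 'source<TAB>target')"
                )
            u, v = parts
            nodes.update((u, v))
            if (u, v) in seen:
                n_dupes += 1
                continue
            seen.add((u, v))
            edges.append((u, v))
    if not nodes:
        raise ValueError(f"{path}: empty edge-list file")
    if n_dupes:
        warnings.warn(f"{path}: collapsed {n_dupes} duplicate edge(s)")
    return Network.from_edges(edges, nodes)


def write_edge_list(path: str | Path, net: Network) -> None:
    with Path(path).open("w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
        for v in sorted(net.nodes - {x for e in net.edges for x in e}):
            fh.write(f"# isolated\t{v}\n")


def _read_isolated(path: Path) -> set[str]:
    out = set()
    with path.open() as fh:
        for raw in fh:
            if raw.startswith("# isolated\t"):
                out.add(raw.rstrip("\n").split("\t", 1)[1])
    return out


def read_network(path: str | Path) -> Network:
    """Edge list plus any ``# isolated`` node annotations written by
    :func:`write_edge_list`."""
    net = read_edge_list(path)
    iso = _read_isolated(Path(path))
    if iso:
        net = Network(net.nodes | frozenset(iso), net.edges)
    return net


def write_hierarchy(path: str | Path, h: Hierarchy) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# M={h.max_level}\n")
        for v in sorted(h.level):
            fh.write(f"{v}\t{h[v]}\n")


def read_hierarchy(path: str | Path) -> Hierarchy:
    path = Path(path)
    max_level = None
    levels: dict[str, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("M="):
                    max_level = int(body[2:])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed line {raw!r}")
            levels[parts[0]] = int(parts[1])
    if max_level is None:
        raise ValueError(f"{path}: missing '# M=<int>' header")
    return Hierarchy(levels, max_level)


def write_sequence(
    outdir: str | Path, seq: EvolvingSequence, prefix: str = "net"
) -> Path:
    """Write each member network plus a JSON manifest; returns the manifest
    path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, net in enumerate(seq):
        name = f"{prefix}_{i:03d}.tsv"
        write_edge_list(outdir / name, net)
        files.append(name)
    manifest = {
        "files": files,
        "tau": seq.tau,
        "meta": seq.meta,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_sequence(manifest_path: str | Path) -> EvolvingSequence:
    mpath = Path(manifest_path)
    doc = json.loads(mpath.read_text())
    nets = [read_network(mpath.parent / name) for name in doc["files"]]
    return EvolvingSequence(nets, tau=doc.get("tau"), meta=doc.get("meta", {}))
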