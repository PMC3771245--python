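"""NEXUS output readable by SplitsTree4 (TAXA, ST_SPLITS, CHARACTERS).

Split systems are written as a SplitsTree ``st_splits`` block: each
split is listed as the 1-based index set of its ``side_a`` taxa with its
weight; the circular ordering, when known (Neighbor-Net), is recorded as
a CYCLE statement. A reader for this dialect supports round-tripping and
the ``gonet compare`` command. Binary encodings are written as a
STANDARD-datatype characters block.
"""

from __future__ import annotations

import re
from pathlib import Path

from .splits import Split, SplitSystem

__all__ = ["write_splits_nexus", "read_splits_nexus", "write_characters_nexus"]


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def write_splits_nexus(
    ss: SplitSystem, path: str | Path, comment: str | None = None
) -> None:
    """Write a split system as a SplitsTree4-readable NEXUS file."""
    taxa = list(ss.taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    lines = ["#nexus"]
    if comment:
        lines.append("[" + comment.replace("]", ")") + "]")
    lines.append("BEGIN Taxa;")
    lines.append(f"DIMENSIONS ntax={len(taxa)};")
    lines.append("TAXLABELS")
    for i, t in enumerate(taxa, start=1):
        lines.append(f"[{i}] {_quote(t)}")
    lines.append(";")
    lines.append("END; [Taxa]")
    lines.append("BEGIN st_splits;")
    lines.append(f"DIMENSIONS ntax={len(taxa)} nsplits={len(ss)};")
    lines.append("FORMAT labels=no weights=yes confidences=no intervals=no;")
    if ss.circular_ordering is not None:
        cyc = " ".join(str(index[t]) for t in ss.circular_ordering)
        lines.append(f"CYCLE {cyc};")
    lines.append("MATRIX")
    ordered = sorted(
        ss.weights.items(),
        key=lambda kv: (sorted(index[t] for t in kv[0].side_a)),
    )
    for k, (s, w) in enumerate(ordered, start=1):
        ids = sorted(index[t] for t in s.side_a)
        id_str = " ".join(str(i) for i in ids)
        lines.append(f"[{k}, size={len(ids)}] \t{w:.10g} \t {id_str},")
    lines.append(";")
    lines.append("END; [st_splits]")
    Path(path).write_text("\n".join(lines) + "\n")


def read_splits_nexus(path: str | Path) -> SplitSystem:
    """Read a split system from the dialect written by :func:`write_splits_nexus`."""
    text = Path(path).read_text()
    text = re.sub(r"\[[^\]]*\]", " ", text)  # strip comments/index tags
    m = re.search(r"TAXLABELS(.*?);", text, re.S | re.I)
    if m is None:
        raise ValueError(f"{path}: no TAXLABELS block")
    taxa = re.findall(r"'((?:[^']|'')*)'|(\S+)", m.group(1))
    labels = [
        (q.replace("''", "'") if q else u) for q, u in taxa if (q or u)
    ]
    cyc_m = re.search(r"CYCLE([^;]*);", text, re.I)
    ordering = None
    if cyc_m:
        ordering = tuple(labels[int(i) - 1] for i in cyc_m.group(1).split())
    mat_m = re.search(r"MATRIX(.*?);", text.split("st_splits", 1)[-1], re.S | re.I)
    if mat_m is None:
        raise ValueError(f"{path}: no splits MATRIX block")
    ss = SplitSystem(tuple(labels), circular_ordering=ordering)
    for entry in mat_m.group(1).split(","):
        toks = entry.split()
        if not toks:
            continue
        w = float(toks[0])
        side = frozenset(labels[int(i) - 1] for i in toks[1:])
        ss.add(Split.of(side, labels), w)
    return ss


def write_characters_nexus(
    taxa: list[str], matrix, path: str | Path, comment: str | None = None
) -> None:
    """Write a 0/1 matrix as a NEXUS STANDARD characters block."""
    lines = ["#nexus"]
    if comment:
        lines.append("[" + comment.replace("]", ")") + "]")
    lines.append("BEGIN Taxa;")
    lines.append(f"DIMENSIONS ntax={len(taxa)};")
    lines.append("TAXLABELS")
    for i, t in enumerate(taxa, start=1):
        lines.append(f"[{i}] {_quote(t)}")
    lines.append(";")
    lines.append("END; [Taxa]")
    lines.append("BEGIN Characters;")
    lines.append(f"DIMENSIONS nchar={matrix.shape[1]};")
    lines.append('FORMAT datatype=standard symbols="01" labels=left;')
    lines.append("MATRIX")
    for t, row in zip(taxa, matrix):
        lines.append(f"{_quote(t)} {''.join(str(int(x)) for x in row)}")
    lines.append(";")
    lines.append("END; [Characters]")
    Path(path).write_text("\n".join(lines) + "\n")
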