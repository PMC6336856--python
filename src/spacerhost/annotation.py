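"""Genome feature records and minimal GFF3 reading/writing.

Coordinates are 0-based half-open internally; GFF3 is written/read with
its native 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Feature:
    """One annotated segment of a genome."""

    name: str
    start: int          # 0-based half-open
    end: int
    strand: str = "+"
    kind: str = "gene"  # "gene" | "intergenic" | "origin" | ...
    seqid: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start


def write_gff3(features: list[Feature], path, source: str = "spacerhost") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.name};Name={f.name}"
            fh.write("\t".join([
                f.seqid, source, f.kind, str(f.start + 1), str(f.end),
                ".", f.strand, ".", attrs]) + "\n")


def read_gff3(path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            name = "."
            for kv in cols[8].split(";"):
                if kv.startswith("Name="):
                    name = kv[5:]
                elif kv.startswith("ID=") and name == ".":
                    name = kv[3:]
            feats.append(Feature(name=name, start=int(cols[3]) - 1, end=int(cols[4]),
                                 strand=cols[6], kind=cols[2], seqid=cols[0]))
    return feats
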