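"""miRNA annotation model and file I/O.

Coordinates are stored 0-based half-open (BED convention) everywhere inside
the package; GFF3 (1-based inclusive) is converted once at the boundary.

The GFF3 dialect follows miRBase: hairpins are ``miRNA_primary_transcript``
features, matures are ``miRNA`` features linked to their hairpin through a
``Derives_from`` attribute.  Polycistronic membership is carried in an
optional ``cluster`` attribute (an extension of the dialect; miRBase encodes
clusters only implicitly through genomic adjacency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "Mature",
    "Hairpin",
    "MiRNAAnnotation",
    "read_gff3",
    "write_gff3",
    "read_bed6",
    "write_bed6",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA hairpin (``miRNA_primary_transcript``)."""

    id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r} for {self.id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval for {self.id}")


@dataclass(frozen=True)
class Mature:
    """A mature miRNA excised from one arm of a hairpin."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    arm: str  # '5p' or '3p'
    hairpin_id: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if self.strand not in "+-":
            raise ValueError(f"unknown strand {self.strand!r} for {self.id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval for {self.id}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MiRNAAnnotation:
    """Hairpin + mature miRNA annotation for one assembly.

    Invariants enforced at construction: unique ids, every mature lies
    within its parent hairpin on the same strand/chromosome, and the two
    arms of a hairpin do not overlap.
    """

    hairpins: dict[str, Hairpin] = field(default_factory=dict)
    matures: dict[str, Mature] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        shared = set(self.hairpins) & set(self.matures)
        if shared:
            raise ValueError(f"ids used for both hairpin and mature: {sorted(shared)}")
        for m in self.matures.values():
            hp = self.hairpins.get(m.hairpin_id)
            if hp is None:
                raise ValueError(
                    f"mature {m.id} Derives_from unknown hairpin {m.hairpin_id}"
                )
            if m.chrom != hp.chrom or m.strand != hp.strand:
                raise ValueError(f"mature {m.id} disagrees with hairpin placement")
            if not (hp.start <= m.start and m.end <= hp.end):
                raise ValueError(f"mature {m.id} extends outside hairpin {hp.id}")
        for hp_id in self.hairpins:
            arms = self.arms_of(hp_id)
            if len(arms) == 2:
                a, b = sorted(arms.values(), key=lambda m: m.start)
                if a.end > b.start:
                    raise ValueError(f"arms of {hp_id} overlap")

    def arms_of(self, hairpin_id: str) -> dict[str, Mature]:
        """Map arm label -> mature for one hairpin."""
        return {
            m.arm: m for m in self.matures.values() if m.hairpin_id == hairpin_id
        }

    def mature_table(self) -> pd.DataFrame:
        """Mature features as a BED-like DataFrame (one row per mature)."""
        rows = [
            {
                "mirna": m.id,
                "chrom": m.chrom,
                "start": m.start,
                "end": m.end,
                "strand": m.strand,
                "arm": m.arm,
                "hairpin": m.hairpin_id,
            }
            for m in self.matures.values()
        ]
        return pd.DataFrame(rows).sort_values(["chrom", "start", "mirna"]).reset_index(
            drop=True
        )

    @property
    def cluster_membership(self) -> dict[str, str]:
        """hairpin id -> polycistron label, for clustered hairpins only."""
        return {
            h.id: h.cluster_id for h in self.hairpins.values() if h.cluster_id
        }


def _fmt_attrs(attrs: Mapping[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(s: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in s.strip().split(";"):
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k.strip()] = v.strip()
    return out


def write_gff3(annotation: MiRNAAnnotation, path) -> None:
    """Write the annotation in miRBase GFF3 dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for hp in sorted(annotation.hairpins.values(), key=lambda h: (h.chrom, h.start)):
            attrs = {"ID": hp.id, "Name": hp.id}
            if hp.cluster_id:
                attrs["cluster"] = hp.cluster_id
            fh.write(
                "\t".join(
                    [
                        hp.chrom,
                        "mirhsr",
                        "miRNA_primary_transcript",
                        str(hp.start + 1),
                        str(hp.end),
                        ".",
                        hp.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for m in sorted(
                (x for x in annotation.matures.values() if x.hairpin_id == hp.id),
                key=lambda m: m.start,
            ):
                fh.write(
                    "\t".join(
                        [
                            m.chrom,
                            "mirhsr",
                            "miRNA",
                            str(m.start + 1),
                            str(m.end),
                            ".",
                            m.strand,
                            ".",
                            _fmt_attrs(
                                {"ID": m.id, "Name": m.id, "Derives_from": m.hairpin_id}
                            ),
                        ]
                    )
                    + "\n"
                )


def read_gff3(path) -> MiRNAAnnotation:
    """Read a miRBase-dialect GFF3 into internal 0-based half-open model.

    Raises ``ValueError`` for a mature whose ``Derives_from`` does not
    resolve, and for unknown strands.
    """
    hairpins: dict[str, Hairpin] = {}
    pend: list[tuple[str, str, int, int, str, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr = fields[:9]
            attrs = _parse_attrs(attr)
            start0, end0 = int(start) - 1, int(end)
            if ftype == "miRNA_primary_transcript":
                hid = attrs["ID"]
                hairpins[hid] = Hairpin(
                    hid, chrom, start0, end0, strand, attrs.get("cluster")
                )
            elif ftype == "miRNA":
                pend.append((attrs["ID"], chrom, start0, end0, strand, attrs["Derives_from"]))
    matures: dict[str, Mature] = {}
    for mid, chrom, s, e, strand, parent in pend:
        if parent not in hairpins:
            raise ValueError(f"mature {mid} Derives_from unknown hairpin {parent}")
        hp = hairpins[parent]
        if mid.endswith("-5p") or mid.endswith("-3p"):
            arm = mid[-2:]
        else:
            # fall back to position relative to the hairpin midpoint
            mid_point = (s + e) / 2
            arm = "5p" if (mid_point - hp.start < hp.end - mid_point) else "3p"
            if strand == "-":
                arm = {"5p": "3p", "3p": "5p"}[arm]
        matures[mid] = Mature(mid, chrom, s, e, strand, arm, parent)
    return MiRNAAnnotation(hairpins=hairpins, matures=matures)


def read_bed6(path) -> pd.DataFrame:
    """Read BED6 (0-based half-open); returns columns chrom..strand."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
        comment="#",
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand in BED record(s): {df.index[bad].tolist()[:5]}")
    return df


def write_bed6(records: pd.DataFrame, path) -> None:
    records.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA -> dict of upper-cased sequences."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
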