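"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA alignments (via Biopython), TSV sample/annotation/trace
tables (via pandas), Newick/NEXUS trees (via dendropy), and YAML config.
All coordinates are 0-based half-open internally; ages are years before
present, with "present" the common sampling time of the modern tips.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from mitoclock.errors import FormatError, ValidationError
from mitoclock.tree import TimeTree

log = logging.getLogger("mitoclock")

# ------------------------------------------------------------------- samples


class SampleClass(str, enum.Enum):
    modern = "modern"
    ancient_AMH = "ancient_AMH"
    archaic = "archaic"
    outgroup = "outgroup"


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced tip: identity, calibrated age ± error, class label.

    ``age_mean`` is the point estimate in years BP (0 for contemporary
    samples); ``age_sd`` the standard error of the calibrated radiocarbon
    date, used as the standard deviation of the normal tip-age prior.
    """

    sample_id: str
    age_mean: float
    age_sd: float
    sample_class: SampleClass

    def __post_init__(self):
        if self.age_mean < 0:
            raise ValidationError(f"{self.sample_id}: negative age {self.age_mean}")
        if self.age_sd < 0:
            raise ValidationError(f"{self.sample_id}: negative age sd {self.age_sd}")
        cls = SampleClass(self.sample_class)
        object.__setattr__(self, "sample_class", cls)
        if cls is SampleClass.modern and self.age_mean != 0:
            raise ValidationError(
                f"{self.sample_id}: modern samples must have age_mean 0"
            )

    @property
    def is_ancient(self) -> bool:
        return self.sample_class in (SampleClass.ancient_AMH, SampleClass.archaic)


def read_sample_table(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "age_mean", "age_sd", "class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids {dups}")
    records = []
    for row in df.to_dict("records"):
        try:
            cls = SampleClass(row["class"])
        except ValueError:
            raise ValidationError(
                f"{row['sample_id']}: unknown class {row['class']!r}"
            ) from None
        records.append(
            SampleRecord(str(row["sample_id"]), float(row["age_mean"]),
                         float(row["age_sd"]), cls)
        )
    return records


def write_sample_table(records, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "age_mean": [r.age_mean for r in records],
            "age_sd": [r.age_sd for r in records],
            "class": [r.sample_class.value for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- alignment

ALPHABET = "ACGTN-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
A, C, G, T, N, GAP = range(6)
AMBIGUOUS = (N, GAP)  # both treated as fully ambiguous in the likelihood


class Alignment:
    """Site matrix over {A,C,G,T,N,-}, rows in a fixed sequence order.

    ``codes`` is an (n_sequences, n_sites) uint8 matrix with the encoding
    A=0 C=1 G=2 T=3 N=4 -=5.
    """

    def __init__(self, ids, codes):
        self.ids = list(ids)
        self.codes = np.asarray(codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise ValidationError("alignment matrix shape does not match ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence ids in alignment")

    @classmethod
    def from_strings(cls, ids, seqs) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise FormatError("ragged alignment")
        arr = np.zeros((len(seqs), lengths.pop() if lengths else 0), dtype=np.uint8)
        for i, s in enumerate(seqs):
            row = np.frombuffer(s.upper().encode(), dtype=np.uint8)
            codes = np.full(row.shape, N, dtype=np.uint8)
            for ch, code in _CODE.items():
                codes[row == ord(ch)] = code
            arr[i] = codes
        return cls(ids, arr)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i) -> str:
        if isinstance(i, str):
            i = self.ids.index(i)
        return "".join(ALPHABET[c] for c in self.codes[i])

    def subset_sites(self, cols) -> "Alignment":
        return Alignment(self.ids, self.codes[:, cols])

    def subset_sequences(self, keep_ids) -> "Alignment":
        idx = [self.ids.index(i) for i in keep_ids]
        return Alignment([self.ids[i] for i in idx], self.codes[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and np.array_equal(self.codes, other.codes)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_sequences}×{self.n_sites})"


def read_alignment(path) -> Alignment:
    """Read a FASTA alignment; case-normalized, non-IUPAC-DNA collapsed to N."""
    path = Path(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise FormatError(f"{path}: no FASTA records found")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        offender = ids[[len(s) for s in seqs].index(max(lengths))]
        raise FormatError(
            f"{path}: ragged sequence lengths (e.g. {offender!r}); "
            "input must be aligned"
        )
    aln = Alignment.from_strings(ids, seqs)
    # report collapsed characters
    for i, s in enumerate(seqs):
        bad = sorted({ch for ch in s if ch not in _CODE})
        if bad:
            warnings.warn(
                f"{ids[i]}: characters {bad} outside {{A,C,G,T,N,-}} collapsed to N"
            )
            log.warning("%s: collapsed %s to N", ids[i], bad)
    return aln


def write_alignment(aln: Alignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for i, sid in enumerate(aln.ids):
            fh.write(f">{sid}\n")
            s = aln.sequence(i)
            for k in range(0, len(s), width):
                fh.write(s[k : k + width] + "\n")


# ---------------------------------------------------------------- annotation

SITE_GROUPS = ("HVS1", "HVS2", "PC1", "PC2", "PC3", "tRNA", "rRNA", "other")

# the K=4 partitioning scheme used throughout the analysis
SCHEME_K4 = {
    "PC1+PC2": ("PC1", "PC2"),
    "PC3": ("PC3",),
    "HVS1+HVS2": ("HVS1", "HVS2"),
    "rRNA+tRNA": ("rRNA", "tRNA"),
}


class SiteAnnotation:
    """Per-column functional group labels for an alignment."""

    def __init__(self, labels):
        labels = np.asarray(labels, dtype="U8")
        bad = set(np.unique(labels)) - set(SITE_GROUPS)
        if bad:
            raise ValidationError(f"unknown site groups {sorted(bad)}")
        self.labels = labels

    @property
    def n_sites(self) -> int:
        return self.labels.shape[0]

    def sites_of(self, groups) -> np.ndarray:
        if isinstance(groups, str):
            groups = (groups,)
        if "all" in groups:
            return np.arange(self.n_sites)
        return np.flatnonzero(np.isin(self.labels, list(groups)))

    def partition_sites(self, scheme=SCHEME_K4) -> dict:
        """Map partition name -> column indices; empty partitions dropped."""
        out = {}
        for name, groups in scheme.items():
            cols = self.sites_of(groups)
            if cols.size:
                out[name] = cols
        return out


def read_site_annotation(path, one_based: bool = False) -> SiteAnnotation:
    """Read a TSV of (start, end, group) intervals.

    Intervals are 0-based half-open by default; pass ``one_based=True`` for
    a 1-based inclusive dialect (converted at this boundary).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"start", "end", "group"}
    if missing := required - set(df.columns):
        raise FormatError(f"site annotation missing columns {sorted(missing)}")
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    if one_based:
        starts = starts - 1  # end inclusive == half-open end
    n = int(ends.max()) if len(ends) else 0
    labels = np.full(n, "other", dtype="U8")
    for s, e, g in zip(starts, ends, df["group"]):
        if s < 0 or e < s:
            raise ValidationError(f"bad interval [{s}, {e})")
        labels[s:e] = g
    return SiteAnnotation(labels)


def write_site_annotation(ann: SiteAnnotation, path) -> None:
    rows = []
    labels = ann.labels
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        rows.append((i, j, labels[i]))
        i = j
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open\n")
        fh.write("start\tend\tgroup\n")
        for s, e, g in rows:
            fh.write(f"{s}\t{e}\t{g}\n")


# --------------------------------------------------------------------- trees


def read_tree(path, schema: str = "newick", time_tree: bool = True, tip_ages=None):
    """Read a tree; ``time_tree=True`` means branch lengths are in years.

    For time trees, node ages are recovered from tip ages (years BP,
    default 0) plus branch lengths and returned as a :class:`TimeTree`.
    Divergence trees (lengths in substitutions/site) are returned as a
    dendropy tree unchanged.
    """
    d = dendropy.Tree.get(path=str(path), schema=schema)
    if not time_tree:
        return d
    return TimeTree.from_dendropy(d, tip_ages=tip_ages)


def write_tree(tree, path, schema: str = "newick") -> None:
    d = tree.to_dendropy() if isinstance(tree, TimeTree) else tree
    d.write(
        path=str(path),
        schema=schema,
        suppress_rooting=(schema == "newick"),
        real_value_format_specifier=".10g",
    )


# -------------------------------------------------------------------- traces


def write_trace(samples: dict, path) -> None:
    """Write a BEAST-style log: state index column + one column per parameter."""
    lengths = {k: len(v) for k, v in samples.items()}
    if len(set(lengths.values())) > 1:
        raise ValidationError(f"mismatched trace lengths {lengths}")
    n = next(iter(lengths.values())) if lengths else 0
    df = pd.DataFrame({"state": np.arange(n)})
    for k, v in samples.items():
        df[k] = np.asarray(v, dtype=float)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trace(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {k: df[k].to_numpy() for k in df.columns if k != "state"}


# -------------------------------------------------------------------- config


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
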