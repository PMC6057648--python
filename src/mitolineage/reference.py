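"""Mitochondrial reference model: genome sequence, feature map, codon context.

Coordinates are 1-based and inclusive throughout, matching the convention used
for mitochondrial variant names (e.g. mt3366 G>A). The genome is treated as
linear for annotation: the mouse control region (NCR, 15423-16299) abuts the
end of the sequence, so no feature wraps the origin.

The packaged mouse feature table carries the real NC_005089/AY172335 gene
coordinates. The sequence of :func:`mouse_scaffold` is *synthetic* — a random
sequence constrained to have plausible coding structure under the vertebrate
mitochondrial genetic code — because annotation logic only needs coordinates
plus a concrete sequence to read codons from.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

HEAVY = "heavy"
LIGHT = "light"

FEATURE_CLASSES = ("protein", "tRNA", "rRNA", "NCR", "ETAS", "CSB")
OXPHOS_COMPLEXES = ("COMI", "COMIII", "COMIV", "COMV", "none")

#: vertebrate mitochondrial genetic code
MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MitoFeature:
    """One annotated feature of the mitochondrial genome."""

    name: str
    feature_class: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = HEAVY
    oxphos_complex: str = "none"

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in (HEAVY, LIGHT):
            raise ValueError(f"strand must be heavy/light, got {self.strand!r}")
        if self.oxphos_complex not in OXPHOS_COMPLEXES:
            raise ValueError(f"unknown OXPHOS complex {self.oxphos_complex!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature bounds [{self.start}, {self.end}]")
        if self.feature_class != "protein" and self.oxphos_complex != "none":
            raise ValueError(
                f"{self.name}: only protein features belong to an OXPHOS complex"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop(self) -> bool:
        """True for protein genes whose stop codon is completed by polyadenylation.

        Several mammalian mtDNA genes (mouse mt-Co3, mt-Nd4, mt-Cytb) end in a
        partial T/TA codon completed to TAA on the mRNA; their genomic length is
        not divisible by 3.
        """
        return self.feature_class == "protein" and self.length % 3 != 0

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class MitoGenome:
    """A mitochondrial genome sequence with its feature map."""

    sequence: str
    features: list[MitoFeature] = field(default_factory=list)
    accession: str = "custom"

    def __post_init__(self):
        self.sequence = str(self.sequence).upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"sequence contains non-ACGT symbols: {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}] outside genome of "
                    f"length {self.genome_length}"
                )

    @property
    def genome_length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        self._check_position(position)
        return self.sequence[position - 1]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.genome_length:
            raise ValueError(
                f"position {position} outside [1, {self.genome_length}]"
            )

    def feature_by_name(self, name: str) -> MitoFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")


def features_at(genome: MitoGenome, position: int) -> list[MitoFeature]:
    """All features whose span contains ``position``, in genome order.

    Intergenic positions return an empty list. Overlapping genes (e.g. the
    mt-Atp8/mt-Atp6 overlap) all appear; downstream annotation treats the
    first in genome order as primary.
    """
    genome._check_position(position)
    return [f for f in genome.features if f.contains(position)]


def codon_context(
    genome: MitoGenome, feature: MitoFeature, position: int
) -> tuple[str, int, str]:
    """Codon, offset-in-codon and strand-corrected base at ``position``.

    The codon is read in coding orientation: light-strand genes are
    reverse-complemented and their reading frame is anchored at ``feature.end``.
    A trailing partial codon (incomplete stop) is padded with A, mirroring
    polyadenylation of the mRNA.

    Returns ``(codon, offset, coding_base)`` where ``offset`` is 0..2 and
    ``coding_base`` is the reference base as seen on the coding strand.
    """
    if feature.feature_class != "protein":
        raise ValueError(f"{feature.name} is not a protein-coding feature")
    if not feature.contains(position):
        raise ValueError(f"position {position} outside {feature.name}")
    if feature.strand == HEAVY:
        idx = position - feature.start
        coding = genome.sequence[feature.start - 1 : feature.end]
        base = genome.base_at(position)
    else:
        idx = feature.end - position
        coding = revcomp(genome.sequence[feature.start - 1 : feature.end])
        base = genome.base_at(position).translate(_COMPLEMENT)
    ci, offset = divmod(idx, 3)
    codon = coding[3 * ci : 3 * ci + 3]
    codon = codon + "A" * (3 - len(codon))  # poly-A completion of partial stop
    return codon, offset, base


# ---------------------------------------------------------------------------
# feature table I/O

_TABLE_COLUMNS = ["name", "class", "start", "end", "strand", "complex"]


def read_feature_table(path) -> list[MitoFeature]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    feats = []
    for _, row in df.iterrows():
        try:
            feats.append(
                MitoFeature(
                    name=row["name"],
                    feature_class=row["class"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    oxphos_complex=row["complex"],
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed feature row {dict(row)}: {exc}") from exc
    return feats


def write_feature_table(features: list[MitoFeature], path) -> None:
    df = pd.DataFrame(
        [
            (f.name, f.feature_class, f.start, f.end, f.strand, f.oxphos_complex)
            for f in features
        ],
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_reference(fasta_path, feature_table_path) -> MitoGenome:
    """Load a genome from a single-record FASTA plus a feature table TSV."""
    record = SeqIO.read(fasta_path, "fasta")  # raises unless exactly one record
    features = read_feature_table(feature_table_path)
    return MitoGenome(
        sequence=str(record.seq), features=features, accession=record.id
    )


def write_fasta(genome: MitoGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.accession}\n")
        for i in range(0, genome.genome_length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# synthetic sequences

MOUSE_GENOME_LENGTH = 16299

_STOPS = set(MITO_TABLE.stop_codons)  # TAA, TAG, AGA, AGG
_SENSE_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - _STOPS)


def mouse_features() -> list[MitoFeature]:
    """The packaged mouse mtDNA feature map (NC_005089 coordinates)."""
    with resources.files("mitolineage.data").joinpath(
        "mouse_mtdna_features.tsv"
    ).open("rb") as fh:
        return read_feature_table(io.BytesIO(fh.read()))


def synthetic_sequence(
    length: int, features: list[MitoFeature], seed: int = 0
) -> str:
    """A random sequence with valid coding structure under the given features.

    Protein genes get a start codon, sense codons internally and a stop (or
    partial stop for length-not-divisible-by-3 genes); where genes overlap the
    later gene in genome order wins, so an upstream gene may carry internal
    stops inside the overlap — harmless for codon-context queries.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        if f.feature_class != "protein":
            continue
        n_full, rem = divmod(f.length, 3)
        codons = ["ATG"]
        codons += list(rng.choice(_SENSE_CODONS, size=max(n_full - 2, 0)))
        if rem == 0:
            codons.append("TAA")
        else:
            codons.append(str(rng.choice(_SENSE_CODONS)))
            codons.append("TA"[:rem])
        cds = "".join(codons)[: f.length]
        if f.strand == LIGHT:
            cds = revcomp(cds)
        seq[f.start - 1 : f.end] = list(cds)
    return "".join(seq)


def mouse_scaffold(seed: int = 0) -> MitoGenome:
    """Mouse-shaped genome: real NC_005089 feature coordinates over a
    synthetic 16,299-bp sequence.

    Gene identity, OXPHOS complex and NCR/ETAS/CSB lookups are faithful to the
    real annotation; codon *content* at any given position is synthetic.
    """
    feats = mouse_features()
    return MitoGenome(
        sequence=synthetic_sequence(MOUSE_GENOME_LENGTH, feats, seed=seed),
        features=feats,
        accession="synthetic-scaffold-NC_005089-coords",
    )


def toy_genome(seed: int = 0) -> MitoGenome:
    """A 900-bp genome with one gene of each class plus an NCR, for fast tests."""
    feats = [
        MitoFeature("toy-Trna", "tRNA", 1, 60),
        MitoFeature("toy-Rrna", "rRNA", 61, 260),
        MitoFeature("toy-Prot", "protein", 271, 570, HEAVY, "COMI"),
        MitoFeature("toy-ProtL", "protein", 581, 700, LIGHT, "COMIV"),
        MitoFeature("toy-NCR", "NCR", 721, 900),
    ]
    return MitoGenome(
        sequence=synthetic_sequence(900, feats, seed=seed),
        features=feats,
        accession="toy",
    )
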