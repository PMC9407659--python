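"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the data behind a CMS-restorer study in rice: a
circular ~457 kb mitochondrial genome carrying a three-part chimeric ORF,
cDNA clone sets with C-to-U editing, RLM-RACE 5' ends concentrated at a
cleavage site, qRT-PCR Ct tables encoding tissue-specific fold differences,
and segregating crosses. Each generator takes an explicit seed and is
byte-deterministic; truth records carry the planted coordinates and rates so
every downstream caller can be scored against them.

Defaults mirror the study conditions: a 457,380 bp genome at 43.83% G+C; a
549 bp chimeric ORF of 421 bp (donor identity 0.79) + 71 bp (identity 1.0)
+ 57 bp (no donor); editing at transcript positions 62 and 65 at rates
0.762 and 0.821; cleavage before nucleotide 415; per-tissue transcript fold
differences {root 3.3, stem 11.5, leaf 8.2, panicle 6.7, anther 8.5}.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from ._io import Genome, Gff3Feature, revcomp, write_fasta, write_gff3

BASES = np.array(["A", "C", "G", "T"])
STOP_CODONS = {"TAA", "TAG", "TGA"}

# a fixed derangement of the alphabet, used to plant guaranteed mismatches
_MISMATCH = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One named generator per operation; no global state."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "big") % (2**32)])
    return np.random.default_rng(ss)


def random_sequence(rng: np.random.Generator, length: int, gc_prob: float) -> str:
    at = (1.0 - gc_prob) / 2.0
    gc = gc_prob / 2.0
    return "".join(rng.choice(BASES, size=length, p=[at, gc, gc, at]))


# ---------------------------------------------------------------------------
# mitogenome + chimeric ORF


@dataclass
class MitoSimParams:
    """Parameters for the mitogenome generator.

    ``genome_length`` is the length of the finished CMS genome (backbone plus
    planted insert); ``chimera_spec`` lists (donor_id or "unknown",
    segment_length, donor_identity or None) triples composing the insert.
    """

    genome_length: int = 457_380
    gc_prob: float = 0.4383
    circular: bool = True
    n_references: int = 3
    ref_divergence: float = 0.005
    chimera_spec: list[tuple[str, int, float | None]] = field(
        default_factory=lambda: [("donorA", 421, 0.79), ("donorB", 71, 1.0), ("unknown", 57, None)]
    )
    insert_position: int = 120_000
    donor_length: int = 50_000
    boundary_window: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 < self.gc_prob < 1.0:
            raise ValueError("gc_prob must lie in (0, 1)")
        total = sum(length for _, length, _ in self.chimera_spec)
        if self.chimera_spec and total % 3 != 0:
            raise ValueError("chimera segment lengths must sum to a codon multiple")
        for donor_id, length, identity in self.chimera_spec:
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            if donor_id != "unknown" and not 0.0 < identity <= 1.0:
                raise ValueError("donor_identity must lie in (0, 1]")
            if donor_id != "unknown" and length > self.donor_length:
                raise ValueError("segment longer than donor sequence")
        if not 0 <= self.insert_position <= self.genome_length - total:
            raise ValueError("insert_position outside the backbone")


def make_chimeric_orf(spec: list[tuple[str, int, float | None]], rng: np.random.Generator) -> str:
    """Build the planted ORF: ATG + stop-free codons + TAA, with the two
    editable codons (Pro CCA at codon 21, Ser TCC at codon 22) fixed so the
    C-to-U edits at transcript positions 62 and 65 change Pro->Leu and
    Ser->Phe.

    Candidate sequences are rejection-sampled until the planted ORF is the
    only open reading frame of >= 50 codons in the insert (random 549 bp
    stretches frequently harbor incidental reverse-strand ORFs, which would
    otherwise confound planted-truth bookkeeping downstream).
    """
    from .orfs import call_orfs

    total = sum(length for _, length, _ in spec)
    n_codons = total // 3
    for _attempt in range(1000):
        codons = ["ATG"]
        while len(codons) < n_codons - 1:
            codon = "".join(rng.choice(BASES, size=3))
            if codon not in STOP_CODONS:
                codons.append(codon)
        codons.append("TAA")
        if n_codons >= 22:
            codons[20] = "CCA"  # codon 21: Pro, middle base = position 62
            codons[21] = "TCC"  # codon 22: Ser, middle base = position 65
        orf = "".join(codons)
        calls = call_orfs(orf, min_aa=min(50, n_codons - 2) if n_codons > 2 else 1)
        if [(c.start, c.end, c.strand) for c in calls] == [(0, total, "+")]:
            return orf
    raise RuntimeError("could not sample a clean chimeric ORF")


def _mutate_identity(
    segment: str, identity: float, window: int, rng: np.random.Generator
) -> str:
    """Return a copy of ``segment`` at the requested nucleotide identity,
    leaving ``window`` bases at each end untouched so seed matches anchor the
    planted boundaries exactly."""
    n_mut = int(round((1.0 - identity) * len(segment)))
    interior = np.arange(window, len(segment) - window)
    if n_mut > len(interior):
        raise ValueError("requested identity too low for boundary windows")
    out = list(segment)
    for pos in rng.choice(interior, size=n_mut, replace=False):
        out[pos] = _MISMATCH[out[pos]]
    return "".join(out)


@dataclass
class MitoTruth:
    """Planted ground truth for one mitogenome fixture."""

    insert_start: int
    insert_end: int
    orf_seq: str
    segments: list[dict]  # orf_start/orf_end (ORF coords), donor_id, donor_start/end, identity

    def to_features(self, seqid: str) -> list[Gff3Feature]:
        feats = []
        if self.insert_end > self.insert_start:
            feats.append(
                Gff3Feature(seqid, "cmsforge_sim", "planted_insert", self.insert_start, self.insert_end, None, "+", ".", {"ID": "insert1"})
            )
        for i, seg in enumerate(self.segments):
            feats.append(
                Gff3Feature(
                    seqid,
                    "cmsforge_sim",
                    "planted_segment",
                    self.insert_start + seg["orf_start"],
                    self.insert_start + seg["orf_end"],
                    seg["identity"],
                    "+",
                    ".",
                    {"ID": f"segment{i + 1}", "Parent": "insert1", "donor": seg["donor_id"]},
                )
            )
        return feats


def generate_mitogenomes(params: MitoSimParams) -> tuple[Genome, list[Genome], list[Genome], MitoTruth]:
    """Generate the CMS genome, a non-CMS reference panel, and the donor
    panel, returning ``(cms, references, donors, truth)``.

    The CMS genome is the reference backbone with the chimeric insert planted
    at ``insert_position``; references carry ``ref_divergence`` substitutions
    per site relative to the backbone; each donor genome embeds the unmutated
    source of its segment flanked by four guaranteed-mismatch bases so local
    hits terminate exactly at the planted boundaries.
    """
    params.validate()
    insert_len = sum(length for _, length, _ in params.chimera_spec)
    backbone_len = params.genome_length - insert_len

    backbone = random_sequence(_rng(params.seed, "backbone"), backbone_len, params.gc_prob)

    segments: list[dict] = []
    if params.chimera_spec:
        orf = make_chimeric_orf(params.chimera_spec, _rng(params.seed, "orf"))
        # force the junction-adjacent backbone bases to mismatch the insert
        # ends, so no k-mer window crossing a junction can chance-match the
        # references and the planted insert is exactly the uncovered interval
        pos = params.insert_position
        bb = list(backbone)
        if pos < len(bb) and bb[pos] == orf[0]:
            bb[pos] = _MISMATCH[bb[pos]]
        if pos > 0 and bb[pos - 1] == orf[-1]:
            bb[pos - 1] = _MISMATCH[bb[pos - 1]]
        backbone = "".join(bb)
        offset = 0
        for donor_id, length, identity in params.chimera_spec:
            segments.append(
                {
                    "donor_id": donor_id,
                    "orf_start": offset,
                    "orf_end": offset + length,
                    "identity": identity if donor_id != "unknown" else None,
                }
            )
            offset += length
        cms_seq = backbone[: params.insert_position] + orf + backbone[params.insert_position :]
    else:
        orf = ""
        cms_seq = backbone
    cms = Genome("cms_query", cms_seq, params.circular)

    references = []
    for i in range(params.n_references):
        rng = _rng(params.seed, f"reference{i}")
        seq = list(backbone)
        n_mut = rng.binomial(backbone_len, params.ref_divergence)
        for pos in rng.choice(backbone_len, size=n_mut, replace=False):
            seq[pos] = _MISMATCH[seq[pos]]
        references.append(Genome(f"ref{i + 1}", "".join(seq), params.circular))

    donors = []
    for seg in segments:
        if seg["donor_id"] == "unknown":
            continue
        rng = _rng(params.seed, f"donor_{seg['donor_id']}")
        source = orf[seg["orf_start"] : seg["orf_end"]]
        # donor carries the *source*; the planted ORF segment diverged from it
        donor_source = _mutate_identity(source, seg["identity"], params.boundary_window, rng)
        body = random_sequence(rng, params.donor_length - len(source) - 8, params.gc_prob)
        pos = int(rng.integers(2000, len(body) - 2000))
        left_context = orf[max(0, seg["orf_start"] - 4) : seg["orf_start"]].rjust(4, "A")
        right_context = orf[seg["orf_end"] : seg["orf_end"] + 4].ljust(4, "A")
        left_flank = "".join(_MISMATCH[b] for b in left_context)
        right_flank = "".join(_MISMATCH[b] for b in right_context)
        donor_seq = body[:pos] + left_flank + donor_source + right_flank + body[pos:]
        seg["donor_start"] = pos + 4
        seg["donor_end"] = pos + 4 + len(source)
        donors.append(Genome(seg["donor_id"], donor_seq, False))

    truth = MitoTruth(
        insert_start=params.insert_position if params.chimera_spec else 0,
        insert_end=params.insert_position + insert_len if params.chimera_spec else 0,
        orf_seq=orf,
        segments=segments,
    )
    return cms, references, donors, truth


# ---------------------------------------------------------------------------
# cDNA clones and RACE ends


@dataclass
class TranscriptSimParams:
    transcript_length: int = 549
    edit_sites: list[tuple[int, float]] = field(
        default_factory=lambda: [(62, 0.762), (65, 0.821)]
    )
    cleavage_position: int = 415  # 1-based downstream nucleotide of the cut
    background_end_fraction: float = 0.1
    n_clones: int = 500
    clone_error_rate: float = 0.0
    seed: int = 0

    def validate(self, orf: str | None = None) -> None:
        for pos, rate in self.edit_sites:
            if not 1 <= pos <= self.transcript_length:
                raise ValueError(f"edit position {pos} outside transcript")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("edit_rate must lie in [0, 1]")
            if orf is not None and orf[pos - 1] != "C":
                raise ValueError(f"edit position {pos} is not a C in the reference")
        if not 2 <= self.cleavage_position <= self.transcript_length:
            raise ValueError("cleavage_position out of range")


def generate_cdna_clones(
    params: TranscriptSimParams, orf: str
) -> tuple[list[tuple[str, str]], dict]:
    """Simulate sequenced cDNA clones of ``orf``.

    Each clone is independently edited C->T at each site with probability
    ``edit_rate`` (C-to-U in mRNA appears as C->T in cDNA), then subjected to
    uniform substitution errors at ``clone_error_rate``. Returns
    ``(clones, truth)`` where clones are (id, sequence) pairs and truth holds
    the realized per-site edited counts.
    """
    params.validate(orf)
    rng = _rng(params.seed, "cdna")
    clones = []
    edited_counts = {pos: 0 for pos, _ in params.edit_sites}
    for i in range(params.n_clones):
        seq = list(orf)
        for pos, rate in params.edit_sites:
            if rng.random() < rate:
                seq[pos - 1] = "T"
                edited_counts[pos] += 1
        if params.clone_error_rate > 0:
            n_err = rng.binomial(len(seq), params.clone_error_rate)
            for pos in rng.choice(len(seq), size=n_err, replace=False):
                seq[pos] = _MISMATCH[seq[pos]]
        clones.append((f"clone{i + 1}", "".join(seq)))
    truth = {
        "edited_counts": edited_counts,
        "n_clones": params.n_clones,
        "true_rates": dict(params.edit_sites),
    }
    return clones, truth


def generate_race_ends(
    params: TranscriptSimParams, transcript: str | None = None
) -> tuple[list[tuple[str, str]], dict]:
    """Simulate RLM-RACE 5'-end clones.

    A fraction ``1 - background_end_fraction`` of clones start exactly at the
    cleavage position (the adapter ligates only to uncapped, cleaved 5'
    ends); the remainder start uniformly at other positions, emulating
    degradation background. Returns ``(clones, truth)``.
    """
    params.validate()
    rng = _rng(params.seed, "race")
    if transcript is None:
        transcript = random_sequence(_rng(params.seed, "race_ref"), params.transcript_length, 0.44)
    starts = []
    for _ in range(params.n_clones):
        if rng.random() < params.background_end_fraction:
            pos = int(rng.integers(1, params.transcript_length + 1))
            while pos == params.cleavage_position:
                pos = int(rng.integers(1, params.transcript_length + 1))
        else:
            pos = params.cleavage_position
        starts.append(pos)
    clones = [
        (f"race{i + 1}", transcript[pos - 1 :]) for i, pos in enumerate(starts)
    ]
    truth = {
        "cleavage_position": params.cleavage_position,
        "starts": starts,
        "n_at_cut": sum(1 for s in starts if s == params.cleavage_position),
    }
    return clones, truth


# ---------------------------------------------------------------------------
# qRT-PCR Ct tables


@dataclass
class CtSimParams:
    tissues: list[str] = field(
        default_factory=lambda: ["root", "stem", "leaf", "panicle", "anther"]
    )
    true_folds: dict[str, float] = field(
        default_factory=lambda: {
            "root": 3.3,
            "stem": 11.5,
            "leaf": 8.2,
            "panicle": 6.7,
            "anther": 8.5,
        }
    )
    target_genes: list[str] = field(default_factory=lambda: ["FA182-1", "FA182-2"])
    reference_gene: str = "Ubiquitin"
    target_base_ct: float = 26.0
    reference_gene_ct: float = 28.0
    ct_noise_sd: float = 0.05
    replicates: int = 3
    sample_group: str = "sterile"
    calibrator_group: str = "restorer"
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be non-negative")
        for tissue, fold in self.true_folds.items():
            if fold < 0:
                raise ValueError(f"fold for {tissue} must be >= 0")


def generate_ct_table(params: CtSimParams):
    """Simulate a long-format qRT-PCR Ct table.

    The sterile-line (sample) target Ct sits at ``target_base_ct``; the
    restorer-line (calibrator) target Ct is higher by log2(fold), so that
    2^(-ddCt) of sample vs calibrator recovers the planted fold. The
    reference gene is flat across groups. Gaussian noise of ``ct_noise_sd``
    cycles is added per replicate.
    """
    import pandas as pd

    params.validate()
    rng = _rng(params.seed, "ct")
    rows = []
    for tissue in params.tissues:
        fold = params.true_folds[tissue]
        for group in (params.sample_group, params.calibrator_group):
            for gene in params.target_genes + [params.reference_gene]:
                if gene == params.reference_gene:
                    mean_ct = params.reference_gene_ct
                elif group == params.sample_group:
                    mean_ct = params.target_base_ct
                else:
                    mean_ct = params.target_base_ct + np.log2(fold) if fold > 0 else 45.0
                for rep in range(1, params.replicates + 1):
                    ct = mean_ct + rng.normal(0.0, params.ct_noise_sd)
                    rows.append(
                        {
                            "sample": group,
                            "tissue": tissue,
                            "gene": gene,
                            "replicate": rep,
                            "ct": round(float(ct), 4),
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# crosses and mapping panels


@dataclass
class CrossSimParams:
    design: str = "testcross_1to1"  # testcross_1to1 | self_3to1 | recombinant_panel
    n_plants: int = 200
    marker_positions: list[int] = field(
        default_factory=lambda: [0, 50_000, 100_000, 150_000, 200_000, 250_000]
    )
    locus_position: int = 130_000
    seed: int = 0

    def validate(self) -> None:
        if self.design not in {"testcross_1to1", "self_3to1", "recombinant_panel"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_plants <= 0:
            raise ValueError("n_plants must be positive")
        if self.design == "recombinant_panel":
            if not self.marker_positions[0] <= self.locus_position <= self.marker_positions[-1]:
                raise ValueError("locus_position outside marker span")


def generate_cross(params: CrossSimParams):
    """Simulate a segregating cross as a genotype/phenotype table.

    testcross_1to1: Rf/rf x rf/rf progeny, fertile iff heterozygous (H);
    self_3to1: Rf/rf selfed, fertile iff carrying >= 1 Rf allele (dominant,
    sporophytic restoration); recombinant_panel: testcross progeny with a
    single recombination breakpoint per plant and marker genotypes (A/H)
    read off the two haplotypes, fertile iff the locus genotype is H.
    """
    import pandas as pd

    params.validate()
    rng = _rng(params.seed, f"cross_{params.design}")
    rows = []
    if params.design == "testcross_1to1":
        for i in range(params.n_plants):
            geno = "H" if rng.random() < 0.5 else "A"
            rows.append(
                {"plant_id": f"p{i + 1}", "locus_genotype": geno,
                 "phenotype": "fertile" if geno == "H" else "sterile"}
            )
    elif params.design == "self_3to1":
        for i in range(params.n_plants):
            alleles = rng.integers(0, 2, size=2)  # 1 = Rf
            n_rf = int(alleles.sum())
            geno = {0: "A", 1: "H", 2: "B"}[n_rf]
            rows.append(
                {"plant_id": f"p{i + 1}", "locus_genotype": geno,
                 "phenotype": "fertile" if n_rf >= 1 else "sterile"}
            )
    else:
        markers = params.marker_positions
        span = markers[-1] - markers[0]
        for i in range(params.n_plants):
            # recombinant gamete: Rf-carrying haplotype up to the breakpoint,
            # non-carrier beyond (or the mirror image); other gamete is rf
            breakpoint = markers[0] + float(rng.random()) * span
            left_carries = bool(rng.random() < 0.5)

            def carries(pos: float) -> bool:
                return left_carries if pos < breakpoint else not left_carries

            row = {"plant_id": f"p{i + 1}"}
            for j, mpos in enumerate(markers):
                row[f"m{j + 1}"] = "H" if carries(mpos) else "A"
            locus_geno = "H" if carries(params.locus_position) else "A"
            row["phenotype"] = "fertile" if locus_geno == "H" else "sterile"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PPR duplication families


@dataclass
class PprFamilyParams:
    n_genes: int = 5
    seq_length: int = 600
    mut_rate: float = 0.01  # substitutions per site per generation
    gc_prob: float = 0.44
    seed: int = 0


def generate_ppr_family(params: PprFamilyParams) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Simulate a tandem PPR gene family by sequential duplication.

    Starting from a single ancestor, each generation duplicates one existing
    gene (the new copy gets the next id) and then mutates every gene at
    ``mut_rate`` per site. Returns ``(sequences, events)`` where events list
    (parent_id, child_id) pairs oldest -> youngest, so the last event is the
    youngest duplication.
    """
    rng = _rng(params.seed, "ppr_family")
    seqs = {"g1": random_sequence(rng, params.seq_length, params.gc_prob)}
    events: list[tuple[str, str]] = []

    def mutate_all() -> None:
        for gid, seq in seqs.items():
            n_mut = rng.binomial(len(seq), params.mut_rate)
            if n_mut:
                out = list(seq)
                for pos in rng.choice(len(seq), size=n_mut, replace=False):
                    out[pos] = _MISMATCH[out[pos]]
                seqs[gid] = "".join(out)

    for i in range(2, params.n_genes + 1):
        parent = f"g{int(rng.integers(1, i))}"
        child = f"g{i}"
        seqs[child] = seqs[parent]
        events.append((parent, child))
        mutate_all()
    return seqs, events


def standalone_transcript(params: TranscriptSimParams) -> str:
    """A random transcript with C planted at the edit positions; used when no
    chimeric ORF is planted in the mitogenome fixture."""
    rng = _rng(params.seed, "transcript_ref")
    seq = list(random_sequence(rng, params.transcript_length, 0.44))
    for pos, _ in params.edit_sites:
        seq[pos - 1] = "C"
    return "".join(seq)


# ---------------------------------------------------------------------------
# packaged fixture


def write_fixture(
    directory: str | os.PathLike,
    mito_params: MitoSimParams | None = None,
    transcript_params: TranscriptSimParams | None = None,
    ct_params: CtSimParams | None = None,
    n_race_clones: int = 200,
) -> dict:
    """Write the default fixture (all generated inputs + truth) into
    ``directory`` and return a manifest dict. Rerunning with the same seeds
    produces byte-identical files."""
    mito_params = mito_params or MitoSimParams()
    transcript_params = transcript_params or TranscriptSimParams()
    ct_params = ct_params or CtSimParams()
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)

    cms, refs, donors, truth = generate_mitogenomes(mito_params)
    write_fasta(os.path.join(directory, "cms_genome.fasta"), [cms])
    write_fasta(os.path.join(directory, "reference_panel.fasta"), refs)
    write_fasta(os.path.join(directory, "donor_panel.fasta"), donors)
    write_gff3(os.path.join(directory, "truth.gff3"), truth.to_features(cms.id))
    transcript_ref = truth.orf_seq or standalone_transcript(transcript_params)
    write_fasta(os.path.join(directory, "orf.fasta"), [Genome("transcript_ref", transcript_ref)])

    clones, cdna_truth = generate_cdna_clones(transcript_params, transcript_ref)
    write_fasta(
        os.path.join(directory, "cdna_clones.fasta"), [Genome(n, s) for n, s in clones]
    )
    race_params = dataclasses.replace(transcript_params, n_clones=n_race_clones)
    race, race_truth = generate_race_ends(race_params, transcript_ref)
    write_fasta(
        os.path.join(directory, "race_ends.fasta"), [Genome(n, s) for n, s in race]
    )

    ct_table = generate_ct_table(ct_params)
    ct_table.to_csv(os.path.join(directory, "ct_table.tsv"), sep="\t", index=False)

    testcross = generate_cross(CrossSimParams(design="testcross_1to1", seed=mito_params.seed))
    testcross.to_csv(os.path.join(directory, "testcross.tsv"), sep="\t", index=False)
    selfed = generate_cross(CrossSimParams(design="self_3to1", n_plants=228, seed=mito_params.seed))
    selfed.to_csv(os.path.join(directory, "self_f2.tsv"), sep="\t", index=False)
    panel = generate_cross(CrossSimParams(design="recombinant_panel", n_plants=60, seed=mito_params.seed))
    panel.to_csv(os.path.join(directory, "recombinant_panel.tsv"), sep="\t", index=False)

    manifest = {
        "mito_params": dataclasses.asdict(mito_params),
        "transcript_params": dataclasses.asdict(transcript_params),
        "ct_params": dataclasses.asdict(ct_params),
        "n_race_clones": n_race_clones,
        "truth": {
            "insert_start": truth.insert_start,
            "insert_end": truth.insert_end,
            "segments": truth.segments,
            "edited_counts": cdna_truth["edited_counts"],
            "cleavage_position": race_truth["cleavage_position"],
            "race_n_at_cut": race_truth["n_at_cut"],
        },
        "files": [
            "cms_genome.fasta", "reference_panel.fasta", "donor_panel.fasta",
            "truth.gff3", "orf.fasta", "cdna_clones.fasta", "race_ends.fasta",
            "ct_table.tsv", "testcross.tsv", "self_f2.tsv", "recombinant_panel.tsv",
        ],
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
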