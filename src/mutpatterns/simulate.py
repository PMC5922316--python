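"""Synthetic genomes, annotations and SNV catalogues with known ground truth.

The generator is the inverse of the analysis stack: it draws mutation
channels from a known signature mixture, places each mutation at a
genome position whose (plus- or minus-strand) trinucleotide context
matches the drawn channel, and optionally plants a transcriptional
strand bias inside genes and rate multipliers inside region sets.
Placement is context-conditional — the position is drawn among matching
contexts — so the generating 96-channel distribution is exact regardless
of genome composition.

Everything is deterministic under (seed, spec), including the bytes of
the FASTA/VCF/BED files written to disk.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import BASES, CHANNELS_96, parse_channel
from .core import COMPLEMENT, Interval, IntervalSet, MutationCatalogue, ReferenceGenome, Snv
from .io import write_bed, write_fasta, write_matrix, write_vcf

logger = logging.getLogger("mutpatterns")

_CODE = {b: i for i, b in enumerate(BASES)}
_MAX_RETRIES = 100


@dataclass
class SimulationSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate a desk-scale somatic-mutation cohort: a 450 kb
    three-chromosome genome at human-like 41% GC, 30 samples with 3,000
    SNVs each drawn from mixtures of 3 well-separated signatures
    (Dirichlet concentration 0.05 gives peaked, signature-like profiles;
    per-sample mixture weights from Dirichlet(0.5) give diverse
    exposures). Strand bias and region multipliers are off unless set.
    """

    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 150_000, "chr3": 100_000}
    )
    gc: float = 0.41
    n_samples: int = 30
    n_signatures: int = 3
    signature_concentration: float = 0.05
    weight_concentration: float = 0.5
    mutations_per_sample: int = 3000
    #: P(pyrimidine on the gene/coding strand) for in-gene placements;
    #: 0.5 = no transcriptional asymmetry
    strand_bias: float | None = None
    #: region label -> rate multiplier relative to background
    region_multipliers: dict | None = None
    n_genes: int = 60
    gene_length: int = 1500
    promoter_length: int = 300
    surveyed_gap_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError(f"GC fraction must be in (0,1), got {self.gc}")
        if self.strand_bias is not None and not 0 < self.strand_bias < 1:
            raise ValueError("strand_bias probability must be in (0,1)")
        if any(length < 1000 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 1000")


def make_genome(chrom_lengths: dict, gc: float = 0.41, seed: int = 0) -> ReferenceGenome:
    """I.i.d. random genome with the stated GC fraction; deterministic under seed."""
    if not 0 < gc < 1:
        raise ValueError(f"GC fraction must be in (0,1), got {gc}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences = {}
    for name, length in chrom_lengths.items():
        codes = rng.choice(4, size=length, p=p)
        sequences[name] = "".join(BASES[c] for c in codes)
    return ReferenceGenome(sequences)


def make_signature_set(
    k: int, seed: int = 0, concentration: float = 0.05, max_pairwise_cosine: float = 0.5
) -> pd.DataFrame:
    """k column-stochastic 96-channel signatures drawn from a Dirichlet.

    Low concentration yields peaked, well-separated profiles. Draws are
    repeated (deterministically) until all pairwise cosines are below
    ``max_pairwise_cosine``; the pairwise cosines are logged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from .signatures import cos_sim_matrix

    rng = np.random.default_rng(seed)
    for attempt in range(50):
        sigs = rng.dirichlet([concentration] * 96, size=k).T
        df = pd.DataFrame(sigs, index=list(CHANNELS_96), columns=[f"TrueSig_{i + 1}" for i in range(k)])
        if k == 1:
            return df
        sim = cos_sim_matrix(df, df).to_numpy()
        off_diag = sim[~np.eye(k, dtype=bool)]
        if off_diag.max() < max_pairwise_cosine:
            logger.info(
                "signature set (seed %d, attempt %d): max pairwise cosine %.3f",
                seed, attempt, off_diag.max(),
            )
            return df
    raise RuntimeError(
        f"could not draw {k} signatures with pairwise cosine < {max_pairwise_cosine}"
    )


def make_annotations(
    genome: ReferenceGenome,
    n_genes: int = 60,
    gene_length: int = 1500,
    seed: int = 0,
    promoter_length: int = 300,
    surveyed_gap_fraction: float = 0.02,
) -> dict[str, IntervalSet]:
    """Random stranded genes, their promoters, and a surveyed set.

    Genes are placed one per equal-width segment so genes and promoters
    never overlap; each promoter abuts its gene immediately 5' of the
    transcription start (upstream on + genes, downstream coordinate-wise
    on - genes). The surveyed set is the genome minus small random gaps
    (default 2% of each chromosome).
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    total = sum(lengths.values())
    genes, promoters = [], []
    gene_id = 0
    footprint = gene_length + 2 * promoter_length
    for chrom, length in lengths.items():
        n_here = max(1, round(n_genes * length / total))
        seg = length // n_here
        if seg < footprint + 2:
            raise ValueError(
                f"cannot pack {n_here} genes of footprint {footprint} into {chrom} ({length} bp)"
            )
        for i in range(n_here):
            offset = int(rng.integers(promoter_length + 1, seg - gene_length - promoter_length))
            start = i * seg + offset
            end = start + gene_length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id += 1
            name = f"gene{gene_id}"
            genes.append(Interval(chrom, start, end, strand, name))
            if strand == "+":
                promoters.append(Interval(chrom, start - promoter_length, start - 1, strand, f"{name}_prom"))
            else:
                promoters.append(Interval(chrom, end + 1, end + promoter_length, strand, f"{name}_prom"))
    surveyed = []
    for chrom, length in lengths.items():
        n_gaps = 10
        gap_len = max(1, int(length * surveyed_gap_fraction / n_gaps))
        gap_starts = np.sort(rng.choice(length - gap_len, size=n_gaps, replace=False) + 1)
        cursor = 1
        for gs in gap_starts:
            if gs > cursor:
                surveyed.append(Interval(chrom, cursor, min(int(gs) - 1, length)))
            cursor = max(cursor, int(gs) + gap_len)
        if cursor <= length:
            surveyed.append(Interval(chrom, cursor, length))
    return {
        "genes": IntervalSet(genes, label="genes"),
        "promoters": IntervalSet(promoters, label="promoters"),
        "surveyed": IntervalSet(surveyed, label="surveyed").merged(),
    }


class ContextIndex:
    """Genome positions grouped by pyrimidine-frame trinucleotide context.

    For every position whose plus-strand centre base is a pyrimidine the
    plus-strand triplet is the context; for purine centres the reverse
    complement is. Each entry stores chromosome ids, 1-based positions
    and whether the pyrimidine sits on the plus strand.
    """

    def __init__(self, genome: ReferenceGenome):
        self.chroms = list(genome.sequences)
        table = np.full(256, 4, dtype=np.int64)
        for b, c in _CODE.items():
            table[ord(b)] = c
        rc_code = np.empty(64, dtype=np.int64)
        for l in range(4):
            for c in range(4):
                for r in range(4):
                    lc, cc, rc = (_CODE[COMPLEMENT[BASES[x]]] for x in (r, c, l))
                    rc_code[16 * l + 4 * c + r] = 16 * lc + 4 * cc + rc
        per_ctx: dict[int, list] = {}
        for ci, chrom in enumerate(self.chroms):
            codes = table[np.frombuffer(genome.sequences[chrom].encode(), dtype=np.uint8)]
            valid = (codes[:-2] < 4) & (codes[1:-1] < 4) & (codes[2:] < 4)
            centre = codes[1:-1]
            trip = 16 * codes[:-2] + 4 * centre + codes[2:]
            pyr_plus = (centre == 1) | (centre == 3)  # C or T on plus strand
            ctx = np.where(pyr_plus, trip, rc_code[np.clip(trip, 0, 63)])
            pos = np.arange(2, len(codes), dtype=np.int64)  # 1-based centre positions
            for code in np.unique(ctx[valid]):
                mask = valid & (ctx == code)
                per_ctx.setdefault(int(code), []).append(
                    (np.full(mask.sum(), ci), pos[mask], pyr_plus[mask])
                )
        self.entries = {
            code: tuple(np.concatenate(parts) for parts in zip(*chunks))
            for code, chunks in per_ctx.items()
        }

    @staticmethod
    def context_code(five: str, centre: str, three: str) -> int:
        return 16 * _CODE[five] + 4 * _CODE[centre] + _CODE[three]

    def positions(self, five: str, centre: str, three: str):
        code = self.context_code(five, centre, three)
        if code not in self.entries:
            raise ValueError(f"no genomic instance of context {five}{centre}{three}")
        return self.entries[code]


def _strand_lookups(annotations):
    genes = annotations["genes"]
    return (
        genes.merged_by_strand("+").point_lookup(),
        genes.merged_by_strand("-").point_lookup(),
    )


def simulate_catalogue(
    genome: ReferenceGenome,
    signatures: pd.DataFrame,
    weights,
    n_mutations: int,
    sample_id: str = "sim",
    seed: int = 0,
    strand_bias: float | None = None,
    annotations: dict | None = None,
    region_multipliers: dict | None = None,
    regions: dict | None = None,
    context_index: ContextIndex | None = None,
) -> tuple[MutationCatalogue, dict]:
    """Simulate one SNV catalogue from a signature mixture.

    Channels are drawn from sum_k w_k sig_k, positions uniformly among
    matching contexts. With ``strand_bias`` set, placements that land in
    an (unambiguously stranded) gene re-choose the pyrimidine strand
    relative to the gene strand with that probability. With
    ``region_multipliers``, placements are accepted by rejection sampling
    so region rates scale by the stated multipliers. Duplicate
    (chrom, pos, alt) draws are retried. Returns the catalogue and a
    ground-truth record.
    """
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any():
        raise ValueError("mixture weights must be non-negative")
    weights = weights / weights.sum()
    mixture = signatures.to_numpy() @ weights
    rng = np.random.default_rng((seed, zlib.crc32(sample_id.encode()) % (2**31)))
    index = context_index or ContextIndex(genome)
    chrom_names = index.chroms

    gene_plus = gene_minus = None
    if strand_bias is not None:
        if annotations is None:
            raise ValueError("strand_bias requires gene annotations")
        gene_plus, gene_minus = _strand_lookups(annotations)

    mult_lookups = []
    max_mult = 1.0
    if region_multipliers:
        if regions is None:
            raise ValueError("region_multipliers requires region interval sets")
        for label, mult in region_multipliers.items():
            mult_lookups.append((regions[label].merged().point_lookup(), float(mult)))
            max_mult = max(max_mult, float(mult))

    channel_counts = rng.multinomial(n_mutations, mixture)
    seen: set[tuple[str, int, str]] = set()
    snvs: list[Snv] = []
    for ch_idx in np.flatnonzero(channel_counts):
        label = CHANNELS_96[ch_idx]
        five, sub, three = parse_channel(label)
        ref_pyr, alt_pyr = sub[0], sub[2]
        chrom_ids, positions, pyr_plus = index.positions(five, ref_pyr, three)
        # split candidate positions by orientation relative to the covering gene
        if strand_bias is not None:
            cat = np.zeros(len(positions), dtype=np.int8)  # 0 outside/ambiguous, 1 unt, 2 trans
            for ci, chrom in enumerate(chrom_names):
                m = chrom_ids == ci
                if not m.any():
                    continue
                on_p = gene_plus.covers_array(chrom, positions[m])
                on_m = gene_minus.covers_array(chrom, positions[m])
                gene_strand_plus = on_p & ~on_m
                gene_strand_minus = on_m & ~on_p
                pyr_p = pyr_plus[m]
                unt = (gene_strand_plus & pyr_p) | (gene_strand_minus & ~pyr_p)
                tra = (gene_strand_plus & ~pyr_p) | (gene_strand_minus & pyr_p)
                vals = np.zeros(m.sum(), dtype=np.int8)
                vals[unt] = 1
                vals[tra] = 2
                cat[m] = vals
            unt_idx = np.flatnonzero(cat == 1)
            tra_idx = np.flatnonzero(cat == 2)
        for _ in range(int(channel_counts[ch_idx])):
            placed = False
            for _attempt in range(_MAX_RETRIES):
                j = int(rng.integers(len(positions)))
                if strand_bias is not None and len(unt_idx) and len(tra_idx):
                    # in-gene draws re-choose the pyrimidine-vs-gene-strand orientation
                    chrom = chrom_names[chrom_ids[j]]
                    in_gene = gene_plus.covers(chrom, int(positions[j])) != gene_minus.covers(
                        chrom, int(positions[j])
                    )
                    if in_gene:
                        pool = unt_idx if rng.random() < strand_bias else tra_idx
                        j = int(pool[rng.integers(len(pool))])
                chrom = chrom_names[chrom_ids[j]]
                pos = int(positions[j])
                if mult_lookups:
                    mult = 1.0
                    for lookup, m_val in mult_lookups:
                        if lookup.covers(chrom, pos):
                            mult = max(mult, m_val)
                    if rng.random() >= mult / max_mult:
                        continue
                if pyr_plus[j]:
                    ref, alt = ref_pyr, alt_pyr
                else:
                    ref, alt = COMPLEMENT[ref_pyr], COMPLEMENT[alt_pyr]
                key = (chrom, pos, alt)
                if key in seen:
                    continue
                seen.add(key)
                snvs.append(Snv(chrom, pos, ref, alt))
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"failed to place a {label} mutation after {_MAX_RETRIES} retries"
                )
    catalogue = MutationCatalogue(sample_id=sample_id, snvs=snvs)
    truth = {
        "sample": sample_id,
        "weights": weights.tolist(),
        "strand_bias": strand_bias,
        "region_multipliers": dict(region_multipliers) if region_multipliers else None,
        "channel_counts": channel_counts.tolist(),
    }
    return catalogue, truth


def simulate_mut_matrix(signatures: pd.DataFrame, weights, n_per_sample: int, seed: int = 0) -> pd.DataFrame:
    """Multinomial 96 x samples count matrix drawn from signature mixtures.

    ``weights`` is samples x signatures; each column of the result is a
    multinomial draw of ``n_per_sample`` mutations from that sample's
    mixture. Equivalent in distribution to the channel counts of
    genome-placed catalogues (placement is context-conditional), but much
    faster when positions are not needed.
    """
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(weights.shape[0]):
        w = weights[i] / weights[i].sum()
        mixture = signatures.to_numpy() @ w
        cols[f"sample_{i + 1}"] = rng.multinomial(n_per_sample, mixture)
    return pd.DataFrame(cols, index=list(signatures.index))


@dataclass
class CohortSimulation:
    """A full synthetic cohort with its ground truth."""

    spec: SimulationSpec
    genome: ReferenceGenome
    annotations: dict
    signatures: pd.DataFrame
    weights: np.ndarray  # samples x signatures
    catalogues: list
    truth: pd.DataFrame


def simulate_cohort(
    spec: SimulationSpec,
    outdir: str | Path | None = None,
    regions: dict | None = None,
) -> CohortSimulation:
    """Generate a complete cohort under the study conditions of ``spec``.

    When ``outdir`` is given, writes genome.fa, per-sample VCFs,
    genes/promoters/surveyed BEDs, the true signature matrix and a truth
    table of per-sample mixture weights.
    """
    genome = make_genome(spec.chrom_lengths, spec.gc, seed=spec.seed)
    annotations = make_annotations(
        genome,
        n_genes=spec.n_genes,
        gene_length=spec.gene_length,
        seed=spec.seed + 1,
        promoter_length=spec.promoter_length,
        surveyed_gap_fraction=spec.surveyed_gap_fraction,
    )
    signatures = make_signature_set(
        spec.n_signatures, seed=spec.seed + 2, concentration=spec.signature_concentration
    )
    rng = np.random.default_rng(spec.seed + 3)
    weights = rng.dirichlet([spec.weight_concentration] * spec.n_signatures, size=spec.n_samples)
    index = ContextIndex(genome)
    if regions is None and spec.region_multipliers:
        regions = {k: v for k, v in annotations.items() if k in spec.region_multipliers}
    catalogues, truth_rows = [], []
    for i in range(spec.n_samples):
        cat, truth = simulate_catalogue(
            genome,
            signatures,
            weights[i],
            spec.mutations_per_sample,
            sample_id=f"sample_{i + 1}",
            seed=spec.seed + 10 + i,
            strand_bias=spec.strand_bias,
            annotations=annotations if spec.strand_bias is not None else None,
            region_multipliers=spec.region_multipliers,
            regions=regions,
            context_index=index,
        )
        catalogues.append(cat)
        truth_rows.append(truth)
    truth = pd.DataFrame(
        np.asarray(weights),
        index=[c.sample_id for c in catalogues],
        columns=list(signatures.columns),
    )
    result = CohortSimulation(
        spec=spec,
        genome=genome,
        annotations=annotations,
        signatures=signatures,
        weights=np.asarray(weights),
        catalogues=catalogues,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        for cat in catalogues:
            write_vcf(cat, outdir / f"{cat.sample_id}.vcf", genome=genome)
        for key in ("genes", "promoters", "surveyed"):
            write_bed(annotations[key], outdir / f"{key}.bed")
        write_matrix(signatures, outdir / "true_signatures.tsv")
        write_matrix(truth, outdir / "true_weights.tsv")
    return result
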