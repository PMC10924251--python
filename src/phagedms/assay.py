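"""Synthetic phage-propagation assays with known ground-truth fitness.

The generator emulates one selection experiment: an uneven plasmid input
library, one effective round of selection in which a variant's expected
output abundance scales as 10**F_true relative to the reference, multinomial
sequencing sampling of both libraries at finite depth, and (optionally)
paired-end reads of the variant amplicon with i.i.d. substitution errors.

The 24-h low-MOI infection of the real assay spans several phage bursts;
here it is collapsed into a single multiplicative enrichment factor, which
is exactly how the net log10 fold-enrichment statistic interprets it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_model import VariantLibrary, WILDTYPE_NAME

PHRED_OFFSET = 33
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class AssaySimConfig:
    """Parameters of one simulated selection experiment.

    ``true_fitness`` maps variant name to F_true (log10 fold-enrichment per
    assay, reference = 0); variants of the library missing from the map are
    treated as reference-like (F_true = 0). ``input_dispersion`` controls
    library unevenness through a symmetric Dirichlet with concentration
    1/dispersion (0 = perfectly even library).
    """

    library: VariantLibrary
    true_fitness: dict[str, float]
    read_depth_input: int = 1_000_000
    read_depth_output: int = 1_000_000
    input_dispersion: float = 0.3
    per_base_error: float = 0.0
    reference: str = WILDTYPE_NAME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_depth_input <= 0 or self.read_depth_output <= 0:
            raise ConfigError("read depths must be positive")
        if not 0 <= self.per_base_error < 0.25:
            raise ConfigError("per_base_error must be in [0, 0.25)")
        if self.input_dispersion < 0:
            raise ConfigError("input_dispersion must be non-negative")
        if self.reference not in self.library.names:
            raise ConfigError(f"reference {self.reference!r} not in library")
        ref_F = self.true_fitness.get(self.reference, 0.0)
        if ref_F != 0.0:
            raise ConfigError(f"reference must have F_true = 0, got {ref_F}")

    @property
    def variant_names(self) -> list[str]:
        return self.library.names

    def fitness_vector(self) -> np.ndarray:
        return np.array([self.true_fitness.get(n, 0.0) for n in self.variant_names])


@dataclass
class SimulatedAssay:
    """Counts plus ground truth from one simulated assay (reads optional)."""

    counts: pd.DataFrame  # variant_name, input_count, output_count
    truth: dict[str, float]
    reference: str
    reads: "PairedReads | None" = None


@dataclass
class PairedReads:
    """In-memory paired-end read bundle for input and output libraries."""

    read_len: int
    r1: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    r2: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


def draw_input_frequencies(config: AssaySimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw input-library frequencies over the library's variants.

    Symmetric Dirichlet with concentration 1/dispersion; dispersion 0 gives
    the exact uniform vector. Frequencies are strictly positive and sum to 1.
    """
    n = len(config.variant_names)
    if config.input_dispersion == 0:
        return np.full(n, 1.0 / n)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    alpha = 1.0 / config.input_dispersion
    freq = rng.dirichlet(np.full(n, alpha))
    # guard against numerically zero components at extreme dispersion
    tiny = np.finfo(float).tiny
    freq = np.clip(freq, tiny, None)
    return freq / freq.sum()


def apply_selection(freq_in: np.ndarray, fitness: np.ndarray) -> np.ndarray:
    """Expected post-selection frequencies: freq_in * 10**F, renormalized.

    Selection composes additively in F: applying F then G equals one
    application of F + G.
    """
    if not np.isclose(freq_in.sum(), 1.0):
        raise ValueError("input frequencies must sum to 1")
    w = freq_in * np.power(10.0, fitness)
    return w / w.sum()


def sample_counts(freq: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial sequencing sample of ``depth`` total reads."""
    if depth <= 0:
        raise ConfigError("sequencing depth must be positive")
    return rng.multinomial(depth, freq / freq.sum())


def simulate_assay(config: AssaySimConfig, with_reads: bool = False,
                   read_len: int = 50) -> SimulatedAssay:
    """Run the full generator: frequencies -> selection -> counts (-> reads)."""
    rng = np.random.default_rng(config.seed)
    freq_in = draw_input_frequencies(config, rng)
    freq_out = apply_selection(freq_in, config.fitness_vector())
    n_in = sample_counts(freq_in, config.read_depth_input, rng)
    n_out = sample_counts(freq_out, config.read_depth_output, rng)
    counts = pd.DataFrame(
        {
            "variant_name": config.variant_names,
            "input_count": n_in,
            "output_count": n_out,
        }
    )
    assay = SimulatedAssay(
        counts=counts,
        truth={n: config.true_fitness.get(n, 0.0) for n in config.variant_names},
        reference=config.reference,
    )
    if with_reads:
        assay.reads = PairedReads(read_len=read_len)
        for lib_key, col in (("input", "input_count"), ("output", "output_count")):
            r1, r2 = emit_reads(
                config.library,
                dict(zip(counts["variant_name"], counts[col])),
                read_len=read_len,
                per_base_error=config.per_base_error,
                rng=rng,
                id_prefix=lib_key,
            )
            assay.reads.r1[lib_key] = r1
            assay.reads.r2[lib_key] = r2
    return assay


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, round(-10 * np.log10(error_rate)))
    return chr(PHRED_OFFSET + int(q))


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b


def iter_read_pairs(
    library: VariantLibrary,
    counts: dict[str, int],
    read_len: int,
    per_base_error: float,
    rng: np.random.Generator,
    min_overlap: int = 10,
    id_prefix: str = "sim",
    chunk_size: int = 200_000,
):
    """Yield one mate pair per counted molecule of the variant amplicon.

    Mate 1 reads the first ``read_len`` bases of the amplicon on the forward
    strand; mate 2 reads the last ``read_len`` bases on the reverse strand.
    Substitution errors are i.i.d. per amplicon base at ``per_base_error``,
    injected per molecule, so the merged mate pair reproduces the erroneous
    amplicon exactly; qualities encode the error rate (capped at Q40).
    Requires 2*read_len − min_overlap >= amplicon length so the mates always
    overlap resolvably. Yields ``(id, seq1, qual1, seq2, qual2)`` lazily in
    chunks of ``chunk_size`` molecules.
    """
    sequences = library.sequences
    amp_len = len(library.target.dna_seq)
    if 2 * read_len - min_overlap < amp_len:
        raise ConfigError(
            f"read geometry infeasible: 2*{read_len} - {min_overlap} < amplicon {amp_len}"
        )
    qual = _phred_char(per_base_error) * read_len
    row_seq: list[np.ndarray] = []
    serial = 0
    pending = 0

    def _flush(rows: list[np.ndarray], start: int):
        mat = np.vstack(rows)
        if per_base_error > 0:
            err = rng.random(mat.shape) < per_base_error
            idx = np.searchsorted(_BASES, mat[err])
            shift = rng.integers(1, 4, size=int(err.sum()))
            mat[err] = _BASES[(idx + shift) % 4]
        m1 = np.ascontiguousarray(mat[:, :read_len])
        m2 = np.ascontiguousarray(_COMP[mat[:, amp_len - read_len :]][:, ::-1])
        for i in range(mat.shape[0]):
            yield (
                f"{id_prefix}:{start + i}",
                m1[i].tobytes().decode(),
                qual,
                m2[i].tobytes().decode(),
                qual,
            )

    for name in library.names:
        c = int(counts.get(name, 0))
        if c <= 0:
            continue
        template = np.frombuffer(sequences[name].encode(), dtype=np.uint8)
        while c > 0:
            take = min(c, chunk_size - pending)
            row_seq.append(np.tile(template, (take, 1)))
            pending += take
            c -= take
            if pending == chunk_size:
                yield from _flush(row_seq, serial)
                serial += pending
                row_seq, pending = [], 0
    if pending:
        yield from _flush(row_seq, serial)


def emit_reads(
    library: VariantLibrary,
    counts: dict[str, int],
    read_len: int,
    per_base_error: float,
    rng: np.random.Generator,
    min_overlap: int = 10,
    id_prefix: str = "sim",
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Materialize :func:`iter_read_pairs` as (r1, r2) FASTQ record lists."""
    r1_list, r2_list = [], []
    for rid, s1, q1, s2, q2 in iter_read_pairs(
        library, counts, read_len, per_base_error, rng, min_overlap, id_prefix
    ):
        r1_list.append((rid, s1, q1))
        r2_list.append((rid, s2, q2))
    return r1_list, r2_list


def emit_reads_to_files(
    library: VariantLibrary,
    counts: dict[str, int],
    read_len: int,
    per_base_error: float,
    rng: np.random.Generator,
    r1_path,
    r2_path,
    min_overlap: int = 10,
    id_prefix: str = "sim",
) -> int:
    """Stream the mate pairs of :func:`iter_read_pairs` to two FASTQ files."""
    from .seqio import _open_text

    n = 0
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        buf1, buf2 = [], []
        for rid, s1, q1, s2, q2 in iter_read_pairs(
            library, counts, read_len, per_base_error, rng, min_overlap, id_prefix
        ):
            buf1.append(f"@{rid}/1\n{s1}\n+\n{q1}\n")
            buf2.append(f"@{rid}/2\n{s2}\n+\n{q2}\n")
            n += 1
            if len(buf1) >= 100_000:
                f1.write("".join(buf1))
                f2.write("".join(buf2))
                buf1, buf2 = [], []
        f1.write("".join(buf1))
        f2.write("".join(buf2))
    return n
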