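"""Synthetic longitudinal TCR repertoires with known ground truth.

The generator emulates the structure of an in-vitro antigen-stimulation
time course: a heavy-tailed baseline clone-size distribution, a small
minority of responder clones whose frequency is multiplied along archetypal
expansion trajectories over the culture (days 0/3/5/10 by default, three
replicate libraries per day), unique-UMI counts with negative-binomial
overdispersion across replicates, and an optional activation-marker-sorted
fraction in which activated clones are enriched.  It can additionally emit
UMI- and MID-tagged paired FASTQ reads so the read-processing stage can be
tested end to end without any external download.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CloneCountTable, CloneKey, SampleMeta

# Deterministic reverse translation: lexicographically smallest codon per AA.
CODON_OF = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}

NT = np.array(list("ACGT"))


def reverse_translate(aa: str) -> str:
    """Fixed-codon reverse translation (one codon per amino acid)."""
    try:
        return "".join(CODON_OF[a] for a in aa)
    except KeyError as exc:
        raise ValueError(f"cannot reverse-translate amino acid {exc}") from exc


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Lognormal:
    """Baseline clone-size law: weights ~ LogNormal(mu, sigma), normalized."""

    mu: float = 0.0
    sigma: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma < 0:
            raise ValueError("lognormal sigma must be >= 0")
        return rng.lognormal(self.mu, self.sigma, size=n)


@dataclass(frozen=True)
class PowerLaw:
    """Baseline clone-size law with Pareto(alpha) tails."""

    alpha: float = 2.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.alpha <= 0:
            raise ValueError("power-law alpha must be > 0")
        return rng.pareto(self.alpha, size=n) + 1.0


@dataclass(frozen=True)
class TrajectoryArchetype:
    """Named expansion profile: frequency multiplier at each timepoint.

    The day-0 multiplier is identically 1 (the baseline defines day 0).
    """

    name: str
    fold_change_per_timepoint: tuple[float, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        f = self.fold_change_per_timepoint
        if not f or abs(f[0] - 1.0) > 1e-12:
            raise ValueError(f"archetype {self.name!r}: day-0 multiplier must be 1")
        if any(x < 0 for x in f):
            raise ValueError(f"archetype {self.name!r}: multipliers must be >= 0")


_CANONICAL_PROFILES: tuple[tuple[str, tuple[float, ...], float], ...] = (
    ("transient_early", (1.0, 6.0, 3.0, 1.5), 0.30),
    ("transient_mid", (1.0, 2.0, 6.0, 2.0), 0.25),
    ("late_expander", (1.0, 1.0, 4.0, 32.0), 0.25),
    ("early_late", (1.0, 4.0, 2.0, 16.0), 0.10),
    ("decliner", (1.0, 0.5, 0.3, 0.2), 0.10),
)


def default_archetypes(timepoints: Sequence[int] = (0, 3, 5, 10)) -> tuple[TrajectoryArchetype, ...]:
    """Responder archetypes mirroring the expansion-profile clusters seen in
    stimulated cultures: transient early/mid peaks, late expanders, an
    early-plus-late profile and decliners.  Canonical profiles are defined on
    a 4-point grid and log-interpolated for other timepoint counts."""
    n = len(timepoints)
    if n < 2:
        raise ValueError("need at least 2 timepoints")
    out = []
    x_new = np.linspace(0.0, 1.0, n)
    x_ref = np.linspace(0.0, 1.0, 4)
    for name, profile, weight in _CANONICAL_PROFILES:
        if n == 4:
            folds = profile
        else:
            folds = tuple(np.exp(np.interp(x_new, x_ref, np.log(profile))))
            folds = (1.0,) + folds[1:]
        out.append(TrajectoryArchetype(name, tuple(folds), weight=weight))
    return tuple(out)


FLAT = "flat"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic time course."""

    n_clones: int = 2000
    baseline_law: Lognormal | PowerLaw = Lognormal(0.0, 1.0)
    timepoints: tuple[int, ...] = (0, 3, 5, 10)
    n_replicates: int = 3
    depth: int = 25000
    responder_fraction: float = 0.05
    archetypes: tuple[TrajectoryArchetype, ...] | None = None
    dispersion: float = 0.05
    sort_enrichment: float = 20.0
    activation_link: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.sort_enrichment < 1:
            raise ValueError("sort_enrichment must be >= 1")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        arch = self.resolved_archetypes()
        for a in arch:
            if len(a.fold_change_per_timepoint) != len(self.timepoints):
                raise ValueError(
                    f"archetype {a.name!r} has {len(a.fold_change_per_timepoint)} "
                    f"multipliers for {len(self.timepoints)} timepoints"
                )
        w = sum(a.weight for a in arch)
        if not math.isclose(w, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"archetype weights must sum to 1, got {w}")

    def resolved_archetypes(self) -> tuple[TrajectoryArchetype, ...]:
        return self.archetypes if self.archetypes is not None else default_archetypes(self.timepoints)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Per-clone ground truth of the simulated repertoire."""

    cdr3_aa: list[str]
    baseline_freq: np.ndarray            # sums to 1
    archetype: list[str]                 # archetype name or "flat"
    multipliers: np.ndarray              # n_clones x n_timepoints
    fold_day_last: np.ndarray            # realized day0 -> last-day multiplier
    activated: np.ndarray                # bool

    @property
    def n_clones(self) -> int:
        return len(self.cdr3_aa)

    def responders(self) -> np.ndarray:
        return np.asarray([a != FLAT for a in self.archetype])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                clone_id=self.cdr3_aa,
                baseline_freq=self.baseline_freq,
                archetype=self.archetype,
                fold_day_last=self.fold_day_last,
                activated=self.activated,
            )
        )


def _random_cdr3s(rng: np.random.Generator, n: int) -> list[str]:
    """Unique CDR3s of the canonical C...F shape, 8-16 aa long."""
    inner_alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(6, 15))
        s = "C" + "".join(rng.choice(inner_alphabet, size=length)) + "F"
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def simulate_truth(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw baseline frequencies, assign responder archetypes and activation."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_clones
    w = config.baseline_law.sample(rng, n)
    baseline = w / w.sum()
    cdr3s = _random_cdr3s(rng, n)

    n_t = len(config.timepoints)
    mult = np.ones((n, n_t))
    archetype = [FLAT] * n
    n_resp = int(round(config.responder_fraction * n))
    arch = config.resolved_archetypes()
    if n_resp > 0:
        responders = rng.choice(n, size=n_resp, replace=False)
        weights = np.array([a.weight for a in arch])
        picks = rng.choice(len(arch), size=n_resp, p=weights / weights.sum())
        for i, k in zip(responders, picks):
            archetype[i] = arch[k].name
            mult[i, :] = arch[k].fold_change_per_timepoint

    fold_last = mult[:, -1].copy()
    expanded = mult[:, -1] > 1.0
    activated = np.zeros(n, dtype=bool)
    if expanded.any():
        activated[expanded] = rng.random(int(expanded.sum())) < config.activation_link
    return SimTruth(
        cdr3_aa=cdr3s,
        baseline_freq=baseline,
        archetype=archetype,
        multipliers=mult,
        fold_day_last=fold_last,
        activated=activated,
    )


def expected_frequencies(truth: SimTruth) -> np.ndarray:
    """Expected clonal frequency per timepoint: baseline x multiplier, renormalized."""
    f = truth.baseline_freq[:, None] * truth.multipliers
    totals = f.sum(axis=0, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("all clone frequencies vanish at some timepoint")
    return f / totals


def _draw_counts(
    rng: np.random.Generator, freq: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    """One replicate library: multinomial if dispersion is 0, else NB."""
    if dispersion == 0.0:
        return rng.multinomial(depth, freq)
    mean = depth * freq
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator | None = None,
    condition: str = "none",
) -> CloneCountTable:
    """Replicate UMI-count libraries for every timepoint (bulk fraction)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    freqs = expected_frequencies(truth)
    cols, metas = [], []
    for j, day in enumerate(config.timepoints):
        for r in range(1, config.n_replicates + 1):
            cols.append(_draw_counts(rng, freqs[:, j], config.depth, config.dispersion))
            metas.append(
                SampleMeta(f"d{day}_r{r}", timepoint=day, replicate=r, condition=condition)
            )
    counts = np.column_stack(cols)
    present = counts.sum(axis=1) > 0
    return CloneCountTable(
        clones=[CloneKey(truth.cdr3_aa[i]) for i in np.nonzero(present)[0]],
        samples=metas,
        counts=counts[present, :],
    )


def sorted_expected_frequencies(truth: SimTruth, config: SimConfig) -> np.ndarray:
    """Expected clone frequencies in the sorted fraction: final-day frequency
    times ``sort_enrichment`` for activated clones, renormalized."""
    day_last = expected_frequencies(truth)[:, -1]
    enriched = day_last * np.where(truth.activated, config.sort_enrichment, 1.0)
    return enriched / enriched.sum()


def simulate_sorted_fraction(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator | None = None,
    condition: str = "none",
) -> CloneCountTable:
    """Activation-marker-sorted triplicate at the final timepoint."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    enriched = sorted_expected_frequencies(truth, config)
    day = config.timepoints[-1]
    cols, metas = [], []
    for r in range(1, config.n_replicates + 1):
        cols.append(_draw_counts(rng, enriched, config.depth, config.dispersion))
        metas.append(
            SampleMeta(
                f"d{day}_sorted_r{r}", timepoint=day, replicate=r,
                condition=condition, fraction="sorted",
            )
        )
    counts = np.column_stack(cols)
    present = counts.sum(axis=1) > 0
    return CloneCountTable(
        clones=[CloneKey(truth.cdr3_aa[i]) for i in np.nonzero(present)[0]],
        samples=metas,
        counts=counts[present, :],
    )


def simulate_experiment(config: SimConfig) -> tuple[SimTruth, CloneCountTable]:
    """Truth + bulk time-course table from a single seed."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    table = simulate_counts(truth, config, rng)
    return truth, table


# ---------------------------------------------------------------------------
# references, barcodes and read emission
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSegment:
    """A V or J reference sequence with its conserved-codon anchor.

    ``anchor`` is the 0-based index of the first base of the conserved codon
    (Cys for V, Phe/Trp for J).
    """

    name: str
    seq: str
    anchor: int

    def __post_init__(self) -> None:
        if not (0 <= self.anchor <= len(self.seq) - 3):
            raise ValueError(f"{self.name}: anchor {self.anchor} outside sequence")


def toy_reference(
    n_v: int = 3, n_j: int = 2, v_len: int = 60, j_len: int = 48, seed: int = 7
) -> tuple[list[ReferenceSegment], list[ReferenceSegment]]:
    """Small deterministic V/J reference panel for simulation and tests.

    V segments end in the conserved Cys codon (TGC, matching the fixed codon
    table) at ``v_len - 3``; J segments start with the conserved Phe codon
    (TTC) at 0, so a clone template is ``V[:anchor] + CDR3nt + J[3:]`` for a
    CDR3 of the canonical C...F form.
    """
    rng = np.random.default_rng(seed)
    v_refs, j_refs = [], []
    for i in range(n_v):
        body = "".join(rng.choice(NT, size=v_len - 3))
        v_refs.append(ReferenceSegment(f"TRBV{i + 1}", body + "TGC", anchor=v_len - 3))
    for i in range(n_j):
        body = "".join(rng.choice(NT, size=j_len - 3))
        j_refs.append(ReferenceSegment(f"TRBJ{i + 1}", "TTC" + body, anchor=0))
    return v_refs, j_refs


def write_reference_fasta(refs: Sequence[ReferenceSegment], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(r.seq), id=r.name, description=f"anchor={r.anchor}") for r in refs
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_reference_fasta(path: str | Path) -> list[ReferenceSegment]:
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        anchor = None
        for token in rec.description.split():
            if token.startswith("anchor="):
                anchor = int(token.split("=", 1)[1])
        if anchor is None:
            raise ValueError(f"{path}: record {rec.id} lacks an anchor= annotation")
        refs.append(ReferenceSegment(rec.id, str(rec.seq).upper(), anchor))
    return refs


def default_mids(sample_ids: Sequence[str], length: int = 8, min_distance: int = 5,
                 seed: int = 11) -> dict[str, str]:
    """Deterministic MID (sample barcode) assignment with pairwise Hamming
    distance >= ``min_distance``."""
    rng = np.random.default_rng(seed)
    mids: list[str] = []
    while len(mids) < len(sample_ids):
        cand = "".join(rng.choice(NT, size=length))
        if all(sum(a != b for a, b in zip(cand, m)) >= min_distance for m in mids):
            mids.append(cand)
    return {mid: sid for mid, sid in zip(mids, sample_ids)}


def write_mid_table(mid_to_sample: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(m, s) for m, s in mid_to_sample.items()], columns=["mid", "sample_id"]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_mid_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mid", "sample_id"}.issubset(df.columns):
        raise ValueError(f"{path}: MID table needs columns 'mid' and 'sample_id'")
    return dict(zip(df["mid"], df["sample_id"]))


@dataclass(frozen=True)
class ReadEmissionConfig:
    """Amplicon layout and error model for FASTQ emission.

    Layout (5'->3' on the merged amplicon): 8-nt MID, 9-nt UMI, then the
    V-CDR3-J template.  Only barcode coordinates are modelled, not primer
    sequences.
    """

    read_length: int = 120
    reads_per_umi: int = 1
    error_rate: float = 0.0
    base_quality: int = 35
    mid_length: int = 8
    umi_length: int = 9
    unique_umis: bool = True   # reject UMI collisions within a sample


def clone_template(
    cdr3_aa: str, v_ref: ReferenceSegment, j_ref: ReferenceSegment
) -> str:
    """Nucleotide template of a clone: V up to its anchor, the reverse-
    translated CDR3 (whose first/last codons realize the anchors), then J
    past its anchor codon."""
    if not (cdr3_aa.startswith("C") and cdr3_aa[-1] in "FW"):
        raise ValueError(
            f"CDR3 {cdr3_aa!r} does not fit the anchored template (must be C...F/W)"
        )
    return v_ref.seq[: v_ref.anchor] + reverse_translate(cdr3_aa) + j_ref.seq[j_ref.anchor + 3:]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def emit_reads(
    table: CloneCountTable,
    v_refs: Sequence[ReferenceSegment],
    j_refs: Sequence[ReferenceSegment],
    mid_to_sample: dict[str, str],
    r1_path: str | Path,
    r2_path: str | Path,
    config: ReadEmissionConfig = ReadEmissionConfig(),
    seed: int = 0,
) -> tuple[Path, Path]:
    """Emit paired FASTQ for every counted molecule of ``table``.

    One fresh UMI per unique molecule, ``reads_per_umi`` read pairs per UMI,
    independent substitution errors per read copy.  V/J are assigned to each
    clone deterministically by hashing the CDR3, so re-emission is stable.
    """
    rng = np.random.default_rng(seed)
    sample_to_mid = {s: m for m, s in mid_to_sample.items()}
    missing = [s for s in table.sample_ids if s not in sample_to_mid]
    if missing:
        raise ValueError(f"no MID assigned for sample(s): {missing}")

    qual = chr(config.base_quality + 33)
    r1_path, r2_path = Path(r1_path), Path(r2_path)
    serial = 0
    r1_records, r2_records = [], []
    for j, sample in enumerate(table.samples):
        mid = sample_to_mid[sample.sample_id]
        used_umis: set[str] = set()
        for i, clone in enumerate(table.clones):
            n_umi = int(table.counts[i, j])
            if n_umi == 0:
                continue
            v_ref = v_refs[zlib.crc32(clone.cdr3_aa.encode()) % len(v_refs)]
            j_ref = j_refs[zlib.crc32(clone.cdr3_aa[::-1].encode()) % len(j_refs)]
            template = clone_template(clone.cdr3_aa, v_ref, j_ref)
            for _ in range(n_umi):
                while True:
                    umi = "".join(rng.choice(NT, size=config.umi_length))
                    if not config.unique_umis or umi not in used_umis:
                        used_umis.add(umi)
                        break
                amplicon = mid + umi + template
                if len(amplicon) < config.read_length:
                    raise ValueError(
                        f"amplicon shorter than read length for clone {clone.clone_id}"
                    )
                for _copy in range(config.reads_per_umi):
                    serial += 1
                    fwd = _mutate(rng, amplicon[: config.read_length], config.error_rate)
                    rev = _mutate(
                        rng, _revcomp(amplicon[-config.read_length:]), config.error_rate
                    )
                    name = f"read{serial}"
                    r1_records.append(f"@{name}/1\n{fwd}\n+\n{qual * len(fwd)}\n")
                    r2_records.append(f"@{name}/2\n{rev}\n+\n{qual * len(rev)}\n")
    r1_path.write_text("".join(r1_records))
    r2_path.write_text("".join(r2_records))
    return r1_path, r2_path
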