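"""Synthetic inputs with known ground truth for every pipeline stage.

The screen this package analyses combines four kinds of raw data: peptide
intensity tables from a label-free membrane-proteome experiment, mature
protein sequences of chaperone (PrsA) and amylase families, promoter-region
nucleotide sequences, and microplate assay readings (kinetic amylase traces,
calibration standards, beta-galactosidase endpoints).  None of those raw
data are published as machine-readable files, so this module generates each
of them from explicit ground truth.  Every generator returns the truth
alongside the data (as a manifest) so downstream results can be asserted
exactly.

All randomness flows from a single integer seed through
:func:`numpy.random.default_rng`; the same seed always yields byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

PEPTIDE_TABLE_COLUMNS = [
    "protein_id",
    "peptide_seq",
    "is_modified",
    "strain_id",
    "replicate_id",
    "intensity",
]


@dataclass(frozen=True)
class ProteomeTruth:
    """Ground truth for one protein in the simulated membrane proteome.

    Parameters
    ----------
    protein_id:
        Accession used in the peptide table.
    n_peptides:
        Number of distinct (tryptic-like) peptides observed for the protein.
    base_abundance:
        Protein abundance in arbitrary intensity units in the reference
        strain (fold change 1).
    fold_change_by_strain:
        Multiplicative abundance change per strain label.  Strains absent
        from the map use fold change 1.
    """

    protein_id: str
    n_peptides: int
    base_abundance: float
    fold_change_by_strain: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_peptides < 1:
            raise ValueError(f"{self.protein_id}: n_peptides must be >= 1")
        if not self.base_abundance > 0:
            raise ValueError(f"{self.protein_id}: base_abundance must be > 0")
        for strain, fold in self.fold_change_by_strain.items():
            if not fold > 0:
                raise ValueError(
                    f"{self.protein_id}: fold change for strain {strain!r} must be > 0"
                )


@dataclass(frozen=True)
class SimulationConfig:
    """Noise and design parameters of the peptide-table simulation.

    ``intensity_cv`` is the coefficient of variation of the multiplicative
    lognormal measurement noise; ``response_sigma`` is the log-scale spread
    of per-peptide ionisation response factors (drawn once per peptide, so
    the top-3 selection downstream is nontrivial); ``missing_rate`` is the
    probability that one peptide intensity is unreported in one replicate
    (missing completely at random); ``modified_fraction`` is the probability
    that a peptide carries a modification and is therefore discarded by the
    quantification pipeline.
    """

    n_replicates: int = 3
    intensity_cv: float = 0.1
    missing_rate: float = 0.05
    modified_fraction: float = 0.05
    response_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for name in ("missing_rate", "modified_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.intensity_cv < 0 or self.response_sigma < 0:
            raise ValueError("dispersions must be nonnegative")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    # tryptic-like: internal residues exclude K/R, C-terminal residue is K or R
    internal = "".join(rng.choice(list("ACDEFGHILMNPQSTVWY"), size=length - 1))
    return internal + rng.choice(["K", "R"])


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_peptide_table(
    truth: Sequence[ProteomeTruth],
    config: SimulationConfig,
    strains: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a search-engine peptide intensity table for several strains.

    Each protein contributes ``n_peptides`` peptides; a peptide's intensity
    in a replicate is ``base_abundance x fold_change x response_factor x
    lognormal noise``.  Peptides flagged modified keep their rows (the
    quantification stage is responsible for discarding them).  Rows lost to
    missingness are simply absent from the table.

    Returns
    -------
    (table, manifest):
        ``table`` is a long-format DataFrame with the columns in
        :data:`PEPTIDE_TABLE_COLUMNS`.  ``manifest`` records the per-peptide
        response factors and modification flags, the strain/replicate
        design, and the input truth, sufficient to recompute every expected
        downstream value.
    """
    if len(truth) == 0:
        raise ValueError("at least one protein is required")
    if strains is None:
        seen: list[str] = []
        for t in truth:
            for s in t.fold_change_by_strain:
                if s not in seen:
                    seen.append(s)
        strains = seen or ["wt"]
    rng = np.random.default_rng(config.seed)

    peptides = []  # (protein_id, peptide_seq, response_factor, is_modified)
    used: set[str] = set()
    for t in truth:
        for _ in range(t.n_peptides):
            while True:
                seq = _random_peptide(rng, int(rng.integers(8, 16)))
                if seq not in used:
                    used.add(seq)
                    break
            factor = (
                float(rng.lognormal(0.0, config.response_sigma))
                if config.response_sigma > 0
                else 1.0
            )
            modified = bool(rng.random() < config.modified_fraction)
            peptides.append((t.protein_id, seq, factor, modified))

    replicate_ids = [f"rep{i + 1}" for i in range(config.n_replicates)]
    rows = []
    for t in truth:
        own = [p for p in peptides if p[0] == t.protein_id]
        for strain in strains:
            fold = t.fold_change_by_strain.get(strain, 1.0)
            for _, seq, factor, modified in own:
                noise = _lognormal_noise(rng, config.intensity_cv, config.n_replicates)
                missing = rng.random(config.n_replicates) < config.missing_rate
                for r, rep in enumerate(replicate_ids):
                    if missing[r]:
                        continue
                    rows.append(
                        (
                            t.protein_id,
                            seq,
                            modified,
                            strain,
                            rep,
                            t.base_abundance * fold * factor * noise[r],
                        )
                    )
    table = pd.DataFrame(rows, columns=PEPTIDE_TABLE_COLUMNS)
    manifest = {
        "truth": list(truth),
        "strains": list(strains),
        "replicate_ids": replicate_ids,
        "peptides": pd.DataFrame(
            peptides,
            columns=["protein_id", "peptide_seq", "response_factor", "is_modified"],
        ),
        "config": config,
    }
    return table, manifest


def generate_sequence_family(
    ancestor_length: int,
    pairwise_substitution_fractions: np.ndarray,
    seed: int,
    names: Sequence[str] | None = None,
    alphabet: str = AMINO_ACIDS,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a family of equal-length sequences of known divergence.

    Member 0 realizes the random ancestor; member ``i`` is the ancestor
    mutated at exactly ``round(f[0, i] * L)`` uniformly chosen positions,
    each substitution drawn from the alphabet excluding the original letter.
    Divergence from member 0 is therefore exact by construction; divergence
    between two mutated members follows from the (independent) overlap of
    their mutation sets.  The realized identity matrix — counted position by
    position over the generated sequences — is returned as the ground truth
    and is authoritative for all downstream checks.

    Returns ``(sequences, realized_identity)`` where ``realized_identity``
    is a symmetric DataFrame of percent identities in [0, 100].
    """
    f = np.asarray(pairwise_substitution_fractions, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError("pairwise_substitution_fractions must be a square matrix")
    if not np.allclose(f, f.T):
        raise ValueError("pairwise_substitution_fractions must be symmetric")
    if (f < 0).any() or (f > 1).any():
        raise ValueError("substitution fractions must lie in [0, 1]")
    n = f.shape[0]
    if names is None:
        names = [f"seq{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("names length must match matrix size")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    ancestor = rng.choice(letters, size=ancestor_length)

    seqs: dict[str, str] = {names[0]: "".join(ancestor)}
    arrays = [ancestor]
    for i in range(1, n):
        n_mut = int(round(f[0, i] * ancestor_length))
        positions = rng.choice(ancestor_length, size=n_mut, replace=False)
        mutant = ancestor.copy()
        for pos in positions:
            choices = letters[letters != ancestor[pos]]
            mutant[pos] = rng.choice(choices)
        arrays.append(mutant)
        seqs[names[i]] = "".join(mutant)

    identity = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            matches = int(np.sum(arrays[i] == arrays[j]))
            identity[i, j] = identity[j, i] = 100.0 * matches / ancestor_length
    return seqs, pd.DataFrame(identity, index=list(names), columns=list(names))


@dataclass(frozen=True)
class MotifImplant:
    """One motif copy placed in a synthetic promoter region.

    ``position`` is the 0-based start of the occupied window on the forward
    strand; minus-strand implants place the reverse complement there.
    ``n_mismatches`` positions of the motif are randomized to a different
    base before placement.
    """

    motif: str
    position: int
    strand: str = "+"
    n_mismatches: int = 0


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_promoter_region(
    length: int,
    implants: Sequence[MotifImplant | tuple],
    seed: int,
) -> tuple[str, list[dict]]:
    """Random nucleotide background with motif copies implanted.

    Each implant contributes one window that, read on its stated strand,
    matches the motif at all but exactly ``n_mismatches`` positions.
    Implants must fit inside the region and must not overlap one another.

    Returns ``(sequence, manifest)``; the manifest lists, per implant, the
    occupied forward-strand interval, strand, planted window and the exact
    match count, ready to be compared with scanner output.
    """
    implants = [i if isinstance(i, MotifImplant) else MotifImplant(*i) for i in implants]
    intervals = []
    for imp in implants:
        if imp.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not 0 <= imp.n_mismatches <= len(imp.motif):
            raise ValueError("n_mismatches out of range")
        start, end = imp.position, imp.position + len(imp.motif)
        if start < 0 or end > length:
            raise ValueError(f"implant at {start} does not fit in region of length {length}")
        for s, e in intervals:
            if start < e and s < end:
                raise ValueError("implanted motifs must not overlap")
        intervals.append((start, end))

    rng = np.random.default_rng(seed)
    bases = np.array(list(NUCLEOTIDES))
    region = rng.choice(bases, size=length)
    manifest = []
    for imp in implants:
        motif = imp.motif.upper()
        planted = list(motif)
        if imp.n_mismatches:
            positions = rng.choice(len(motif), size=imp.n_mismatches, replace=False)
            for pos in positions:
                choices = bases[bases != planted[pos]]
                planted[pos] = rng.choice(choices)
        window = "".join(planted)
        forward = window if imp.strand == "+" else reverse_complement(window)
        region[imp.position : imp.position + len(motif)] = list(forward)
        manifest.append(
            {
                "motif": motif,
                "start": imp.position,
                "end": imp.position + len(motif),
                "strand": imp.strand,
                "planted_window": window,
                "n_matches": len(motif) - imp.n_mismatches,
            }
        )
    return "".join(region), manifest


def generate_kinetic_traces(
    true_slopes: Sequence[float],
    n_timepoints: int = 7,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 0.05,
) -> pd.DataFrame:
    """Linear A405-vs-time traces, one sample per true slope.

    The default 7 timepoints are minutes 0..6, matching a 6-minute kinetic
    read with one measurement per minute.  Gaussian noise of standard
    deviation ``noise_sd`` is added independently per reading.
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(seed)
    times = np.arange(n_timepoints, dtype=float)
    rows = []
    for k, slope in enumerate(true_slopes):
        values = baseline + slope * times
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=n_timepoints)
        for t, a in zip(times, values):
            rows.append((f"sample{k + 1}", t, a))
    return pd.DataFrame(rows, columns=["sample", "time_min", "absorbance"])


def generate_calibration_series(
    concentrations: Sequence[float],
    response_per_unit: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Calibration standards: kinetic-slope response vs known concentration.

    Emulates a standard series of 0-500 concentration units whose measured
    response (absorbance slope) rises linearly with concentration.
    """
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be nonnegative")
    rng = np.random.default_rng(seed)
    response = intercept + response_per_unit * conc
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame({"concentration": conc, "response": response})


def generate_bgal_readings(
    true_miller_units: Sequence[float],
    od600: Sequence[float],
    t_min: float = 15.0,
    volume_ml: float = 0.1,
    seed: int = 0,
    a550: float = 0.02,
    noise_sd: float = 0.0,
    scatter_factor: float = 1.75,
) -> pd.DataFrame:
    """Endpoint beta-galactosidase readings implied by true Miller units.

    A420 is back-computed from the Miller formula (with the ``scatter_factor``
    x A550 debris correction) so that the noiseless table converts exactly
    back to ``true_miller_units``.
    """
    units = np.asarray(true_miller_units, dtype=float)
    od = np.asarray(od600, dtype=float)
    if units.shape != od.shape:
        raise ValueError("true_miller_units and od600 must have equal length")
    if (od <= 0).any():
        raise ValueError("od600 must be positive")
    if t_min <= 0 or volume_ml <= 0:
        raise ValueError("t_min and volume_ml must be positive")
    rng = np.random.default_rng(seed)
    a420 = units * t_min * volume_ml * od / 1000.0 + scatter_factor * a550
    if noise_sd > 0:
        a420 = a420 + rng.normal(0.0, noise_sd, size=a420.size)
    return pd.DataFrame(
        {
            "sample": [f"sample{i + 1}" for i in range(units.size)],
            "od600": od,
            "a420": a420,
            "a550": np.full(units.size, float(a550)),
            "time_min": np.full(units.size, float(t_min)),
            "volume_ml": np.full(units.size, float(volume_ml)),
        }
    )


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_manifest(manifest: dict, path) -> None:
    """Sidecar manifest as JSON; DataFrames and dataclasses are expanded."""

    def default(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if hasattr(obj, "__dataclass_fields__"):
            return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Mapping):
            return dict(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=default)
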