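"""Synthetic corpora with planted taxonomy, divergence structure and masking.

The generator builds a balanced lineage tree (families > genera > species),
evolves sequences along it with a substitution-only model, assigns release
dates, masks a controlled share of annotations down to kingdom level (or to a
partial depth), and attaches journal/country metadata.  A ground-truth oracle
classifies every kingdom-masked record from the TRUE memberships and dates
alone, independent of any pipeline clustering.

Divergence semantics (expected pairwise divergence between members):

* ``d_intra``   — two members of the same species diverge by about 2*d_intra;
* ``d_species`` — two species of the same genus;
* ``d_genus``   — two species in different genera of the same family;
* ``d_family``  — members of different families (plus the within-family part).

Mutations use fixed counts (round(rate * length) positions drawn without
replacement), so realized divergences sit tightly on their targets and the
planted clusters are recoverable by construction.  Guards at config time
enforce the recoverability margins against the 97%/80% identity thresholds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .audit import AvailabilityPolicy, Classification
from .corpus import Lineage, Rank, RANKS, SequenceRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "TruthEntry",
    "generate_corpus",
    "oracle_classify",
    "mix_config",
    "PLACEHOLDER_MYCOLOGY_JOURNALS",
    "PLACEHOLDER_OTHER_JOURNALS",
]

#: Clearly-labelled placeholder journal names for fixtures (the real curated
#: mycology-journal list is user-supplied configuration, never shipped).
PLACEHOLDER_MYCOLOGY_JOURNALS = (
    "Placeholder Mycology Bulletin",
    "Annals of Synthetic Mycology",
    "Fixture Fungal Ecology",
    "Synthetic Mycological Research",
    "Placeholder Fungal Systematics",
)

PLACEHOLDER_OTHER_JOURNALS = (
    "General Science Letters",
    "Synthetic Soil Biology",
    "Placeholder Environmental Microbiology",
    "Journal of Fixture Ecology",
    "Synthetic Applied Genetics",
)

DEFAULT_COUNTRIES = {
    "Sweden": 0.25,
    "Estonia": 0.20,
    "United States": 0.20,
    "Brazil": 0.15,
    "China": 0.20,
}

#: Two reserved full lineages used by fixtures and worked-example tests.
FIXTURE_LINEAGE_AMANITA = Lineage(
    ("Fungi", "Basidiomycota", "Agaricomycetes", "Agaricales", "Amanitaceae",
     "Amanita", "Amanita muscaria")
)
FIXTURE_LINEAGE_CANTHARELLUS = Lineage(
    ("Fungi", "Basidiomycota", "Agaricomycetes", "Cantharellales", "Cantharellaceae",
     "Cantharellus", "Cantharellus cibarius")
)

_DEFAULT_DEPTH_MASK = {
    Rank.SPECIES: 0.55,
    Rank.GENUS: 0.15,
    Rank.FAMILY: 0.10,
    Rank.ORDER: 0.08,
    Rank.CLASS: 0.07,
    Rank.PHYLUM: 0.05,
}

# Identity guard rails: planted species must stay inside the close-match
# radius and planted families inside / outside the compound radius.
_CLOSE_IDENTITY_GUARD = 0.97
_COMPOUND_IDENTITY_GUARD = 0.80


@dataclass(frozen=True)
class SimConfig:
    """Knobs for one synthetic corpus; fully deterministic given ``seed``."""

    seed: int = 0
    n_families: int = 4
    genera_per_family: int = 2
    species_per_genus: int = 2
    seqs_per_species: int = 8
    seq_length: int = 550
    d_intra: float = 0.005
    d_species: float = 0.10
    d_genus: float = 0.15
    d_family: float = 0.45
    date_start: dt.date = dt.date(2001, 1, 1)
    date_end: dt.date = dt.date(2020, 12, 31)
    # Masking: whole families and whole species can be "dark" (every record
    # kingdom-masked); remaining records are masked independently.  Dark
    # groups are drawn by quota — round(p * n_groups) groups chosen at random
    # — so the planted class mix is stable across seeds.  ``mix_config``
    # tunes these so the planted TP/FN_CLOSE/FN_REASONABLE mix approximates
    # (0.10, 0.73, 0.17) on a dense corpus.
    p_kingdom_mask: float = 0.12
    p_dark_family: float = 0.0
    p_dark_species: float = 0.0
    depth_mask_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_DEPTH_MASK))
    p_myc: float = 0.22
    p_journal_missing: float = 0.30
    countries: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRIES))
    p_country_missing: float = 0.20

    @property
    def n_records(self) -> int:
        return (
            self.n_families
            * self.genera_per_family
            * self.species_per_genus
            * self.seqs_per_species
        )

    def __post_init__(self) -> None:
        for name in ("p_kingdom_mask", "p_dark_family", "p_dark_species", "p_myc",
                     "p_journal_missing", "p_country_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if min(self.n_families, self.genera_per_family, self.species_per_genus,
               self.seqs_per_species, self.seq_length) < 1:
            raise ValueError("tree counts and seq_length must be positive")
        if self.date_start > self.date_end:
            raise ValueError("date_start must not be after date_end")
        if self.depth_mask_distribution:
            if any(w < 0 for w in self.depth_mask_distribution.values()):
                raise ValueError("depth_mask_distribution weights must be non-negative")
            if sum(self.depth_mask_distribution.values()) <= 0:
                raise ValueError("depth_mask_distribution must have positive mass")
        # Recoverability guards against the fixed 97% / 80% identity radii.
        if not 2 * self.d_intra < 1 - _CLOSE_IDENTITY_GUARD:
            raise ValueError("d_intra too large: within-species identity would drop below 97%")
        if not self.d_family > 1 - _COMPOUND_IDENTITY_GUARD:
            raise ValueError("d_family too small: families would not separate below 80% identity")
        if not self.d_species > (1 - _CLOSE_IDENTITY_GUARD) + 4 * self.d_intra:
            raise ValueError("d_species too small: species would merge at the close radius")
        if not self.d_species <= self.d_genus:
            raise ValueError("d_species must not exceed d_genus")
        if not self.d_genus + 2 * self.d_intra < 1 - _COMPOUND_IDENTITY_GUARD:
            raise ValueError("d_genus too large: families would split at the compound radius")


@dataclass(frozen=True)
class TruthEntry:
    accession: str
    species_id: str
    compound_id: str
    true_lineage: Lineage
    classification: Optional[Classification]  # None for non-query records


@dataclass
class GroundTruth:
    """Planted memberships plus oracle classifications for every record."""

    entries: dict[str, TruthEntry]

    @property
    def class_fractions(self) -> dict[str, Optional[float]]:
        queries = [e for e in self.entries.values() if e.classification is not None]
        n = len(queries)
        return {
            c.value: (
                sum(1 for e in queries if e.classification is c) / n if n else None
            )
            for c in Classification
        }

    @property
    def n_queries(self) -> int:
        return sum(1 for e in self.entries.values() if e.classification is not None)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write("accession\tspecies_id\tcompound_id\ttrue_lineage\tclassification\n")
            for acc in sorted(self.entries):
                e = self.entries[acc]
                cls = e.classification.value if e.classification else ""
                handle.write(
                    f"{acc}\t{e.species_id}\t{e.compound_id}\t"
                    f"{e.true_lineage.to_string()}\t{cls}\n"
                )


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute round(rate * len) distinct positions to a different base."""
    n_mut = int(round(rate * seq.shape[0]))
    if n_mut == 0:
        return seq.copy()
    out = seq.copy()
    positions = rng.choice(seq.shape[0], size=n_mut, replace=False)
    # Offset 1..3 modulo 4 always yields a different base.
    offsets = rng.integers(1, 4, size=n_mut)
    out[positions] = (out[positions] + offsets) % 4
    return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode("ascii")


def _choose_weighted(rng: np.random.Generator, weights: dict):
    keys = list(weights)
    probs = np.asarray([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def generate_corpus(config: SimConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Generate a corpus and its ground truth.

    Independent RNG streams are used for sequences, dates, masking and
    metadata, so changing one knob perturbs only its own stream.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_seq = np.random.default_rng(streams[0])
    rng_date = np.random.default_rng(streams[1])
    rng_mask = np.random.default_rng(streams[2])
    rng_meta = np.random.default_rng(streams[3])

    # Branch rates realizing the pairwise divergence targets on a star-ish tree.
    branch_family = config.d_family / 2.0
    branch_genus = (config.d_genus - config.d_species) / 2.0
    branch_species = config.d_species / 2.0

    root = rng_seq.integers(0, 4, size=config.seq_length, dtype=np.int64)

    # Quota-based dark-group selection keeps the planted mix stable.
    n_dark_fam = int(round(config.p_dark_family * config.n_families))
    dark_families = set(
        rng_mask.choice(config.n_families, size=n_dark_fam, replace=False).tolist()
    )
    lit_families = [f for f in range(config.n_families) if f not in dark_families]
    species_per_family = config.genera_per_family * config.species_per_genus
    n_dark_sp = int(round(config.p_dark_species * len(lit_families) * species_per_family))
    n_dark_sp = min(n_dark_sp, len(lit_families))
    # One dark species per chosen family at most, so a family never goes
    # fully dark by accident (which would turn its queries into TPs).
    chosen_fams = rng_mask.choice(len(lit_families), size=n_dark_sp, replace=False)
    dark_species = set()
    for i in chosen_fams.tolist():
        f = lit_families[i]
        k = int(rng_mask.integers(species_per_family))
        dark_species.add((f, k // config.species_per_genus, k % config.species_per_genus))

    records: list[SequenceRecord] = []
    entries: dict[str, TruthEntry] = {}
    n_days = (config.date_end - config.date_start).days
    idx = 0
    for f in range(config.n_families):
        family_dark = f in dark_families
        family_anc = _mutate(root, branch_family, rng_seq)
        family_lineage = (
            "Fungi", f"Phylum_{f}", f"Class_{f}", f"Order_{f}", f"Family_{f}"
        )
        compound_id = f"FAM{f:04d}"
        for g in range(config.genera_per_family):
            genus_anc = _mutate(family_anc, branch_genus, rng_seq)
            genus_name = f"Genus_{f}_{g}"
            for s in range(config.species_per_genus):
                species_anc = _mutate(genus_anc, branch_species, rng_seq)
                species_name = f"{genus_name} species_{s}"
                species_id = f"SP{f:04d}_{g:02d}_{s:02d}"
                true_lineage = Lineage(family_lineage + (genus_name, species_name))
                species_dark = (f, g, s) in dark_species
                for _ in range(config.seqs_per_species):
                    accession = f"SYN{idx:06d}"
                    idx += 1
                    seq = _mutate(species_anc, config.d_intra, rng_seq)
                    release = config.date_start + dt.timedelta(
                        days=int(rng_date.integers(0, n_days + 1))
                    )
                    # Masking: dark family/species force kingdom-only; else an
                    # independent coin, else a partial observation depth.
                    if family_dark or species_dark or (
                        rng_mask.random() < config.p_kingdom_mask
                    ):
                        observed = true_lineage.truncated(Rank.KINGDOM)
                    elif config.depth_mask_distribution:
                        depth = _choose_weighted(rng_mask, config.depth_mask_distribution)
                        observed = true_lineage.truncated(Rank(depth))
                    else:
                        observed = true_lineage

                    if rng_meta.random() < config.p_myc:
                        journal = PLACEHOLDER_MYCOLOGY_JOURNALS[
                            rng_meta.integers(len(PLACEHOLDER_MYCOLOGY_JOURNALS))
                        ]
                    elif rng_meta.random() < config.p_journal_missing:
                        journal = None
                    else:
                        journal = PLACEHOLDER_OTHER_JOURNALS[
                            rng_meta.integers(len(PLACEHOLDER_OTHER_JOURNALS))
                        ]
                    if rng_meta.random() < config.p_country_missing:
                        country = None
                    else:
                        country = _choose_weighted(rng_meta, config.countries)
                    study_id = f"ST{rng_meta.integers(max(3, config.n_records // 20)):04d}"

                    records.append(
                        SequenceRecord(
                            accession=accession,
                            sequence=_to_str(seq),
                            release_date=release,
                            lineage=observed,
                            country=country,
                            journal=journal,
                            study_id=study_id,
                        )
                    )
                    entries[accession] = TruthEntry(
                        accession=accession,
                        species_id=species_id,
                        compound_id=compound_id,
                        true_lineage=true_lineage,
                        classification=None,
                    )

    truth = GroundTruth(entries=entries)
    classifications = oracle_classify(records, truth, AvailabilityPolicy())
    truth.entries = {
        acc: replace(e, classification=classifications.get(acc))
        for acc, e in entries.items()
    }
    return records, truth


def oracle_classify(
    records: Sequence[SequenceRecord],
    truth: GroundTruth,
    policy: AvailabilityPolicy,
) -> dict[str, Classification]:
    """Classify kingdom-masked records from TRUE memberships and dates only.

    Never consults any pipeline clustering: FN_CLOSE needs an available record
    of the same planted species with an observed annotation beyond kingdom,
    FN_REASONABLE the same for the planted compound (family) group, else TP.
    """
    annotated = [
        r for r in records
        if (d := r.lineage.depth()) is not None and d > Rank.KINGDOM
    ]
    out: dict[str, Classification] = {}
    for query in records:
        if not query.lineage.is_kingdom_level():
            continue
        q_truth = truth.entries[query.accession]
        found_close = False
        found_reasonable = False
        for ref in annotated:
            if ref.accession == query.accession:
                continue
            if not policy.is_available(ref.release_date, query.release_date):
                continue
            r_truth = truth.entries[ref.accession]
            if r_truth.species_id == q_truth.species_id:
                found_close = True
                break
            if r_truth.compound_id == q_truth.compound_id:
                found_reasonable = True
        if found_close:
            out[query.accession] = Classification.FN_CLOSE
        elif found_reasonable:
            out[query.accession] = Classification.FN_REASONABLE
        else:
            out[query.accession] = Classification.TP
    return out


def mix_config(seed: int, n_families: int = 21, seq_length: int = 300) -> SimConfig:
    """Preset corpus (~1000 records) whose planted class mix approximates the
    (FN_CLOSE, FN_REASONABLE, TP) = (0.73, 0.17, 0.10) target."""
    return SimConfig(
        seed=seed,
        n_families=n_families,
        genera_per_family=1,
        species_per_genus=2,
        seqs_per_species=24,
        seq_length=seq_length,
        p_kingdom_mask=0.55,
        p_dark_family=0.04,
        p_dark_species=0.08,
    )
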