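"""Synthetic mock-library and environmental ASV datasets with known ground truth.

The generator emulates denoised V9 amplicon output (~130 nt ASVs):

* **Mock libraries** — one per sequencing library: nine expected species at
  designed read proportions, plus low-abundance noise (single-mismatch error
  variants of expected sequences and unrelated contaminants at edit distance
  ≥ 2). Reads are drawn multinomially so per-sample totals are fixed — read
  proportions are the unit the thresholds act on.
* **Environmental samples** — three islands × seven depth strata. Each
  sample's community is the union of a shared core pool, a depth-zone pool
  and an island pool; per-ASV abundances follow a log-normal model with
  per-sample noise. ASV sequences are derived from reference-database entries
  at designed identity levels (exact, >98%, 80–98%, <80%) so the identity
  cutoffs downstream are exercised.

Ground truth (designed thresholds, pool memberships, lineages, functional
classes) is recorded before any sampling noise, sufficient to score recovery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import edit_distance, global_align
from .io import CountMatrix, SampleMetadata, DEFAULT_DEPTH_STRATA
from .records import SequenceRecord, TaxonomyLineage, parse_lineage

BASES = np.array(list("ACGT"))

#: depth-zone grouping used for ordination/PermANOVA (three assemblages)
DEPTH_ZONES = {50: "sublittoral", 150: "upper_bathyal", 300: "upper_bathyal",
               500: "upper_bathyal", 1000: "lower_bathyal", 1500: "lower_bathyal",
               2000: "lower_bathyal"}

#: depth grouping used for the unique/shared ASV accounting (five groups)
DEPTH_SHARING_GROUPS = {50: "50", 150: "150", 300: "300-500", 500: "300-500",
                        1000: "1000-1500", 1500: "1000-1500", 2000: "2000"}

DEFAULT_ISLANDS = ("Flores", "Terceira", "SantaMaria")

# division cycle for synthetic lineages: six heterotroph divisions plus the
# excluded groups (metazoa, fungi, streptophytes, a phototroph placeholder)
_DIVISION_CYCLE = (
    ("Alveolata", "Dinoflagellata"),
    ("Alveolata", "Ciliophora"),
    ("Rhizaria", "Radiolaria"),
    ("Excavata", "Discicristata"),
    ("Stramenopiles", "Stramenopiles_X"),
    ("Opisthokonta", "Choanoflagellida"),
    ("Opisthokonta", "Metazoa"),
    ("Opisthokonta", "Fungi"),
    ("Archaeplastida", "Streptophyta"),
    ("Archaeplastida", "Chlorophyta"),
)

HETEROTROPH_DIVISIONS = frozenset(d for _, d in _DIVISION_CYCLE[:6])


@dataclass
class GroundTruth:
    """Designed quantities recorded before sampling noise."""

    thresholds: dict = field(default_factory=dict)        # library → designed lenient/strict
    asv_info: pd.DataFrame | None = None                  # per-ASV pool/role, lineage, class, identity
    sample_composition: dict = field(default_factory=dict)  # sample → designed (eligible) ASV ids
    reference_db: list | None = None                      # the reference records ASVs derive from


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute ``n_subs`` distinct positions (edit distance ≤ n_subs, = in practice)."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


def generate_reference_db(n_taxa: int, seq_len: int = 130, seed: int = 0) -> list[SequenceRecord]:
    """Random V9-like reference database with PR2-style eight-rank lineages.

    Sequences are mutually distinct with all pairwise identities < 95%;
    divisions cycle through six heterotroph groups and the four excluded
    groups (Metazoa, Fungi, Streptophyta, Chlorophyta).
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be ≥ 1")
    if seq_len < 50:
        raise ValueError("seq_len must be ≥ 50 (V9-like)")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    for i in range(n_taxa):
        for _ in range(200):
            cand = _random_seq(rng, seq_len)
            if all(global_align(cand, s).identity_pct < 95.0 for s in seqs):
                seqs.append(cand)
                break
        else:
            raise ValueError(
                f"could not draw {n_taxa} sequences with pairwise identity < 95% at length {seq_len}"
            )
    records = []
    for i, s in enumerate(seqs):
        supergroup, division = _DIVISION_CYCLE[i % len(_DIVISION_CYCLE)]
        lineage = parse_lineage(
            f"Eukaryota;{supergroup};{division};{division}_X;order_{i};family_{i};genus_{i};species_{i}"
        )
        records.append(SequenceRecord(f"ref_{i:04d}", s, lineage))
    return records


# ---------------------------------------------------------------------------
# Mock libraries

@dataclass
class MockDesign:
    """Designed composition of one mock-community sample.

    ``expected_props`` are the designed read proportions of the nine expected
    species; ``error_variants`` lists (parent index, proportion) pairs for
    1-mismatch variants; ``contaminant_props`` are proportions of unrelated
    sequences at edit distance ≥ 2 from every expected species. Proportions
    must be positive and sum to ≤ 1 (any remainder is drawn and discarded).
    """

    expected_seqs: Sequence[SequenceRecord]
    expected_props: Sequence[float]
    error_variants: Sequence[tuple[int, float]] = ()
    contaminant_props: Sequence[float] = ()
    total_reads: int = 100_000
    seed: int = 0
    sample_id: str = "mock1"

    def __post_init__(self) -> None:
        if len(self.expected_seqs) != len(self.expected_props):
            raise ValueError("one proportion per expected species required")
        props = [*self.expected_props, *(p for _, p in self.error_variants), *self.contaminant_props]
        if any(p <= 0 for p in props):
            raise ValueError("all designed proportions must be > 0")
        if sum(props) > 1 + 1e-12:
            raise ValueError(f"designed proportions sum to {sum(props):.4f} > 1")
        for idx, _ in self.error_variants:
            if not 0 <= idx < len(self.expected_seqs):
                raise ValueError(f"error variant parent index {idx} out of range")

    @property
    def n_expected(self) -> int:
        return len(self.expected_seqs)


def default_mock_species(seed: int = 0, n: int = 9, seq_len: int = 130) -> list[SequenceRecord]:
    """Nine distinct mock species sequences (pairwise identity < 95%)."""
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    while len(seqs) < n:
        cand = _random_seq(rng, seq_len)
        if all(global_align(cand, s).identity_pct < 95.0 for s in seqs):
            seqs.append(cand)
    return [SequenceRecord(f"mocksp_{i + 1}", s) for i, s in enumerate(seqs)]


def default_mock_design(seed: int = 0, total_reads: int = 100_000,
                        sample_id: str = "mock1",
                        species: Sequence[SequenceRecord] | None = None) -> MockDesign:
    """Symmetric nine-species mix with one error variant (0.5%) and one
    contaminant (1%); the expected species share the remaining 98.5% equally,
    so designed proportions sum to exactly 1."""
    if species is None:
        species = default_mock_species(seed)
    noise = 0.005 + 0.01
    return MockDesign(
        expected_seqs=species,
        expected_props=[(1.0 - noise) / len(species)] * len(species),
        error_variants=[(0, 0.005)],
        contaminant_props=[0.01],
        total_reads=total_reads,
        seed=seed,
        sample_id=sample_id,
    )


def generate_mock_library(design: MockDesign) -> tuple[CountMatrix, list[SequenceRecord], GroundTruth]:
    """Draw one mock sample's ASV table from a :class:`MockDesign`.

    Returns the one-sample count matrix (zero-count ASVs dropped, as a
    denoiser would), the ASV sequences and the ground truth: the designed
    lenient threshold (smallest designed proportion among expected ∪ error
    variants) and the designed strict bound (largest designed proportion among
    non-expected ASVs), both on the observed-read scale when the designed
    proportions sum to < 1.
    """
    rng = np.random.default_rng(design.seed)
    expected = list(design.expected_seqs)

    asvs: list[tuple[str, str, str, str | None, float]] = []  # id, seq, role, parent, prop
    for i, (sp, p) in enumerate(zip(expected, design.expected_props)):
        asvs.append((f"{design.sample_id}_asv_e{i + 1}", sp.seq, "expected", sp.id, p))
    for j, (idx, p) in enumerate(design.error_variants):
        parent = expected[idx]
        for _ in range(100):
            var = _mutate(rng, parent.seq, 1)
            if edit_distance(var, parent.seq) == 1 and all(var != a[1] for a in asvs):
                break
        else:  # pragma: no cover - 1-sub mutants of a fixed parent cannot all collide
            raise RuntimeError("could not construct a distinct 1-mismatch variant")
        asvs.append((f"{design.sample_id}_asv_v{j + 1}", var, "variant", parent.id, p))
    for k, p in enumerate(design.contaminant_props):
        for _ in range(200):
            cand = _random_seq(rng, len(expected[0].seq))
            if all(edit_distance(cand, sp.seq) >= 2 for sp in expected) and all(cand != a[1] for a in asvs):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not construct a contaminant at distance ≥ 2")
        asvs.append((f"{design.sample_id}_asv_c{k + 1}", cand, "contaminant", None, p))

    props = np.array([a[4] for a in asvs])
    kept_mass = props.sum()
    p_full = np.append(props, max(0.0, 1.0 - kept_mass))
    draws = rng.multinomial(design.total_reads, p_full / p_full.sum())[: len(asvs)]

    observed = draws > 0
    ids = [a[0] for a in asvs]
    counts = pd.DataFrame([draws[observed]], index=[design.sample_id],
                          columns=[i for i, o in zip(ids, observed) if o])
    seqs = [SequenceRecord(a[0], a[1]) for a, o in zip(asvs, observed) if o]

    # ground truth on the observed-read scale: designed proportions renormalized
    # by the kept mass (identity when the design sums to 1)
    norm = props / kept_mass
    matched = [r in ("expected", "variant") for _, _, r, _, _ in asvs]
    non_expected = [r != "expected" for _, _, r, _, _ in asvs]
    designed_lenient = float(norm[matched].min())
    designed_strict = float(norm[non_expected].max()) if any(non_expected) else 0.0
    designed_feasible = (not any(non_expected)) or designed_strict < norm[
        [r == "expected" for _, _, r, _, _ in asvs]].min()

    info = pd.DataFrame(
        {"role": [a[2] for a in asvs], "parent": [a[3] for a in asvs], "designed_prop": norm,
         "observed": observed},
        index=ids,
    )
    gt = GroundTruth(
        thresholds={design.sample_id: {"lenient": designed_lenient, "strict": designed_strict,
                                       "feasible": bool(designed_feasible)}},
        asv_info=info,
    )
    return CountMatrix(counts), seqs, gt


# ---------------------------------------------------------------------------
# Environmental dataset

@dataclass
class EnvDesign:
    """Design of the synthetic environmental dataset (3 islands × 7 depths).

    Community structure is planted through three disjoint ASV pools: a core
    pool shared by all samples, one pool per depth zone and one per island;
    a sample draws only from the pools consistent with its labels, and each
    eligible ASV occupies a given sample with probability ``occupancy`` — pool
    membership sets the envelope, not a guaranteed occurrence (benthic
    communities are patchy). Abundances are log-normal (``sigma`` across ASVs,
    ``sample_sigma`` per-sample noise).
    ``excluded_fraction`` of the ASVs derive from non-heterotroph references;
    ``identity_fractions`` controls how far ASV sequences are mutated from
    their source reference (exact / >98% / 80–98% / <80%).
    """

    islands: Sequence[str] = DEFAULT_ISLANDS
    depth_strata: Sequence[int] = DEFAULT_DEPTH_STRATA
    depth_zones: dict = field(default_factory=lambda: dict(DEPTH_ZONES))
    core_size: int = 60
    zone_size: int = 40
    island_size: int = 30
    sigma: float = 1.0
    sample_sigma: float = 0.5
    occupancy: float = 0.8
    reads_per_sample: int = 500_000
    excluded_fraction: float = 0.15
    identity_fractions: tuple[float, float, float, float] = (0.25, 0.20, 0.40, 0.15)
    n_libraries: int = 5
    seq_len: int = 130
    n_ref_taxa: int = 120
    seed: int = 0
    reference_db: Sequence[SequenceRecord] | None = None

    def __post_init__(self) -> None:
        if self.core_size + self.zone_size + self.island_size == 0:
            raise ValueError("all pool sizes are zero — nothing to simulate")
        if abs(sum(self.identity_fractions) - 1.0) > 1e-9:
            raise ValueError("identity_fractions must sum to 1")
        if not 0 < self.occupancy <= 1:
            raise ValueError("occupancy must be in (0, 1]")
        missing = set(self.depth_strata) - set(self.depth_zones)
        if missing:
            raise ValueError(f"depth strata without a zone: {sorted(missing)}")


# substitutions per identity category at 130 nt: 0 → 100%, 2 → 98.46%,
# 13 → 90%, 35 → 73% (safely below the 80% cutoff even if the optimal
# alignment recovers a few edits)
_CATEGORY_SUBS = {"exact": 0, "high": 2, "mid": 13, "low": 35}


def _category_counts(n: int, fractions: Sequence[float]) -> list[int]:
    counts = [int(np.floor(f * n)) for f in fractions]
    for i in range(n - sum(counts)):
        counts[i % len(counts)] += 1
    return counts


def generate_env_dataset(design: EnvDesign) -> tuple[CountMatrix, list[SequenceRecord],
                                                     SampleMetadata, GroundTruth]:
    """Generate the 21-sample environmental dataset with planted structure."""
    rng = np.random.default_rng(design.seed)
    refs = list(design.reference_db) if design.reference_db is not None else \
        generate_reference_db(design.n_ref_taxa, design.seq_len, seed=int(rng.integers(2**31)))

    zones = sorted(set(design.depth_zones[d] for d in design.depth_strata))
    pools: dict[str, int] = {"core": design.core_size}
    pools.update({f"zone:{z}": design.zone_size for z in zones})
    pools.update({f"island:{i}": design.island_size for i in design.islands})

    n_total = sum(pools.values())
    n_excluded = int(round(design.excluded_fraction * n_total))
    het_refs = [r for r in refs if r.lineage.division in HETEROTROPH_DIVISIONS]
    exc_refs = [r for r in refs if r.lineage.division not in HETEROTROPH_DIVISIONS]
    if n_excluded > 0 and not exc_refs:
        raise ValueError("excluded_fraction > 0 but the reference db has no excluded divisions")

    # per-ASV functional origin: excluded ASVs spread evenly over the pools
    asv_rows = []
    pool_of: list[str] = []
    for pool, size in pools.items():
        pool_of.extend([pool] * size)
    excluded_flags = np.zeros(n_total, dtype=bool)
    if n_excluded:
        excluded_flags[rng.choice(n_total, size=n_excluded, replace=False)] = True

    categories = sum(([cat] * c for cat, c in
                      zip(_CATEGORY_SUBS, _category_counts(n_total, design.identity_fractions))), [])
    rng.shuffle(categories)

    # exact-category ASVs must map to distinct references (identical sequences
    # would otherwise collide); mutated categories may reuse references
    het_cycle = itertools.cycle(rng.permutation(len(het_refs)))
    exc_cycle = itertools.cycle(rng.permutation(len(exc_refs))) if exc_refs else None
    used_exact: set[str] = set()
    seen_seqs: set[str] = set()
    seqs: list[SequenceRecord] = []
    for i in range(n_total):
        source_refs = exc_refs if excluded_flags[i] else het_refs
        cycle = exc_cycle if excluded_flags[i] else het_cycle
        cat = categories[i]
        for _ in range(10 * len(source_refs) + 100):
            ref = source_refs[next(cycle) % len(source_refs)]
            if cat == "exact":
                if ref.id in used_exact:
                    continue
                seq = ref.seq
            else:
                seq = _mutate(rng, ref.seq, _CATEGORY_SUBS[cat])
            if seq not in seen_seqs:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not derive a distinct ASV sequence")
        if cat == "exact":
            used_exact.add(ref.id)
        seen_seqs.add(seq)
        asv_id = f"asv_{i:04d}"
        seqs.append(SequenceRecord(asv_id, seq))
        asv_rows.append((asv_id, pool_of[i], ref.id, cat,
                         ref.lineage.division,
                         "heterotroph" if not excluded_flags[i] else "excluded"))
    info = pd.DataFrame(asv_rows, columns=["asv", "pool", "ref_id", "identity_category",
                                           "division", "functional_class"]).set_index("asv")

    # sample layout: islands × depth strata, libraries assigned round-robin
    meta_rows, sample_ids = [], []
    for t, island in enumerate(design.islands):
        for depth in design.depth_strata:
            sid = f"env_{island}_{depth}"
            sample_ids.append(sid)
            meta_rows.append((sid, island, depth, f"T{t + 1}", "", "environmental"))
    libraries = [f"L{(k % design.n_libraries) + 1}" for k in range(len(sample_ids))]
    meta_rows = [(sid, isl, d, tr, lib, role)
                 for (sid, isl, d, tr, _, role), lib in zip(meta_rows, libraries)]
    for lib in sorted(set(libraries)):
        meta_rows.append((f"mock_{lib}", "mock", 0, "none", lib, "mock"))
    meta_df = pd.DataFrame(meta_rows, columns=["sample", "island", "depth_m", "transect",
                                               "library_id", "sample_role"]).set_index("sample")
    meta = SampleMetadata(meta_df, tuple(design.depth_strata))

    # log-normal abundance: a base weight per ASV plus per-sample noise
    base_w = rng.lognormal(mean=0.0, sigma=design.sigma, size=n_total)
    asv_index = {a: i for i, a in enumerate(info.index)}
    counts = pd.DataFrame(0, index=sample_ids, columns=list(info.index), dtype=np.int64)
    composition: dict[str, list[str]] = {}
    for sid in sample_ids:
        island = meta.table.loc[sid, "island"]
        zone = design.depth_zones[int(meta.table.loc[sid, "depth_m"])]
        eligible = info.index[(info["pool"] == "core")
                              | (info["pool"] == f"zone:{zone}")
                              | (info["pool"] == f"island:{island}")]
        composition[sid] = list(eligible)
        idx = np.array([asv_index[a] for a in eligible])
        occupied = rng.random(len(idx)) < design.occupancy
        if not occupied.any():  # pragma: no cover - vanishing probability at default sizes
            occupied[rng.integers(len(idx))] = True
        w = base_w[idx] * rng.lognormal(0.0, design.sample_sigma, size=len(idx)) * occupied
        draws = rng.multinomial(design.reads_per_sample, w / w.sum())
        counts.loc[sid, eligible] = draws
    cm = CountMatrix(counts).drop_empty_asvs()
    observed = set(cm.asv_ids)
    seqs = [s for s in seqs if s.id in observed]
    gt = GroundTruth(asv_info=info, sample_composition=composition, reference_db=refs)
    return cm, seqs, meta, gt


def generate_study(seed: int = 0, env_design: EnvDesign | None = None,
                   mock_total_reads: int = 100_000) -> dict:
    """Generate a complete synthetic study: reference db, environmental dataset
    and one mock library per sequencing library, with combined metadata.

    Returns a dict with keys ``refs``, ``env_counts``, ``env_seqs``, ``meta``,
    ``env_truth``, ``mocks`` (library → (CountMatrix, seqs, GroundTruth)) and
    ``mock_species``.
    """
    rng = np.random.default_rng(seed)
    design = env_design if env_design is not None else EnvDesign(seed=int(rng.integers(2**31)))
    if design.reference_db is None:
        design.reference_db = generate_reference_db(design.n_ref_taxa, design.seq_len,
                                                    seed=int(rng.integers(2**31)))
    env_counts, env_seqs, meta, env_truth = generate_env_dataset(design)
    species = default_mock_species(seed=int(rng.integers(2**31)), seq_len=design.seq_len)
    mocks = {}
    for lib in sorted(set(meta.mocks()["library_id"])):
        d = default_mock_design(seed=int(rng.integers(2**31)), total_reads=mock_total_reads,
                                sample_id=f"mock_{lib}", species=species)
        mocks[lib] = generate_mock_library(d)
    return {"refs": list(design.reference_db), "env_counts": env_counts, "env_seqs": env_seqs,
            "meta": meta, "env_truth": env_truth, "mocks": mocks, "mock_species": species}
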