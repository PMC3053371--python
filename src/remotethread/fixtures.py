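"""Deterministic synthetic fixtures for the whole pipeline.

Every input the detection pipeline and the benchmark consume — profile
databases, structure libraries with reference sequences, domain-to-structure
maps, proteomes with planted domains, ortholog tables, essential-residue
annotations, background Z-score samples — can be generated from a single
seeded :class:`FixtureSpec`, so the full system is testable offline.

The generators emulate the statistical structure the method assumes: domain
families whose members diverge by per-site substitution biased toward
BLOSUM62-plausible replacements (so that sequence similarity decays faster
than the detectability of the underlying fold, mirroring the premise that
structure outlasts sequence); structure libraries in which each family's
reference sequences stay close to the family consensus while decoy entries
are unrelated random sequences; and orthologs that are lightly re-diverged
copies of each query protein.

Remote members are *engineered*: the generator searches a divergence grid
and keeps the first divergence at which the planted member's E-value, as
measured by the package's own search engine in full protein context, falls
inside the remote band, and re-diverges orthologs until the domain is
re-detectable at the ortholog E-value ceiling.  Ground truth records what
was planted where and what the construction guarantees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .formats import (
    ALPHABET,
    DomainProfile,
    SequenceRecord,
    StructureEntry,
    write_background_zscores,
    write_clan_map,
    write_essential_residues,
    write_fasta,
    write_ortholog_table,
    write_profiles,
    write_structure_manifest,
    write_structure_map,
)
from .preprocess import extract_domain_region, preprocess_sequence
from .scoring import EmpiricalCDF, score_threading
from .search import DomainHit, SearchConfig, calibrate_profile, search_domains
from .threader import StructureLibrary, thread, top_window

logger = logging.getLogger(__name__)

_B62 = substitution_matrices.load("BLOSUM62")

#: Per-residue substitution proposal, softmax of BLOSUM62 scores at T=2,
#: self-substitution excluded.
_PROPOSAL: dict[str, np.ndarray] = {}
for _a in ALPHABET:
    w = np.array([np.exp(float(_B62[_a, _b]) / 2.0) if _b != _a else 0.0 for _b in ALPHABET])
    _PROPOSAL[_a] = w / w.sum()


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded description of one complete synthetic study.

    The defaults are the study conditions under which the end-to-end
    behaviour of the pipeline is asserted; see docs/methods.md for the
    reasoning behind each value.
    """

    seed: int = 0
    n_families: int = 6
    profile_length: tuple[int, int] = (55, 70)
    members_per_family: int = 20
    member_divergence: float = 0.03
    profile_pseudocount: float = 0.1
    n_structures_per_profile: int = 1
    structure_ref_divergence: float = 0.10
    library_size: int = 1000
    n_significant_proteins: int = 40
    n_remote_proteins: int = 8
    n_remote_with_orthologs: int = 5
    n_decoy_proteins: int = 100
    flank_length: int = 40
    remote_divergence_grid: tuple[float, ...] = (0.70, 0.72, 0.75, 0.78, 0.80)
    remote_evalue_band: tuple[float, float] = (0.3, 20.0)
    ortholog_divergence: float = 0.03
    species: tuple[str, ...] = ("sp1", "sp2", "sp3")
    background_z_count: int = 100_000
    calibration_n: int = 500
    n_essential_positions: int = 8


@dataclass
class FamilyFixture:
    accession: str
    clan: Optional[str]
    consensus: str
    profile: DomainProfile  # uncalibrated until generate_bundle calibrates


@dataclass(frozen=True)
class PlantedDomain:
    """Ground truth for one planted family member."""

    protein_id: str
    accession: str
    start: int
    end: int
    divergence: float
    kind: str  # "significant" | "remote"
    has_orthologs: bool = False
    evalue_measured: Optional[float] = None


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    families: list[FamilyFixture]
    profiles: list[DomainProfile]  # calibrated
    library: StructureLibrary
    structure_map: dict[str, set[str]]
    clan_map: dict[str, str]
    background: np.ndarray
    cdf: EmpiricalCDF
    proteome: list[SequenceRecord]
    ortholog_table: dict[str, dict[str, str]]
    ortholog_sequences: dict[str, SequenceRecord]
    essentials: dict[str, list[tuple[int, str]]]
    truth: list[PlantedDomain]

    def profile_by_accession(self, accession: str) -> DomainProfile:
        for p in self.profiles:
            if p.accession == accession:
                return p
        raise KeyError(accession)


# ---------------------------------------------------------------------------
# elementary generators


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-site substitution at the given rate, BLOSUM62-biased replacements."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        a = out[i]
        if a not in _PROPOSAL:
            continue
        out[i] = ALPHABET[rng.choice(len(ALPHABET), p=_PROPOSAL[a])]
    return "".join(out)


def build_profile(
    members: Sequence[str],
    accession: str,
    name: Optional[str] = None,
    clan: Optional[str] = None,
    db_version: str = "v1",
    pseudocount: float = 0.5,
) -> DomainProfile:
    """Per-position log-odds profile from equal-length, ungapped members."""
    lengths = {len(m) for m in members}
    if len(lengths) != 1:
        raise ValueError("members must share a single length")
    L = lengths.pop()
    counts = np.full((L, len(ALPHABET)), pseudocount)
    idx = {aa: i for i, aa in enumerate(ALPHABET)}
    for m in members:
        for j, c in enumerate(m):
            if c in idx:
                counts[j, idx[c]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    scores = np.log2(freqs * len(ALPHABET))  # odds against uniform background
    return DomainProfile(
        accession=accession,
        name=name or accession,
        clan=clan,
        length=L,
        match_scores=scores,
        db_version=db_version,
    )


def gen_profile_family(
    rng: np.random.Generator,
    spec: FixtureSpec,
    index: int,
    clan: Optional[str] = None,
) -> FamilyFixture:
    """A random consensus plus a profile built from lightly diverged members."""
    lo, hi = spec.profile_length
    L = int(rng.integers(lo, hi + 1))
    consensus = random_sequence(rng, L)
    members = [
        diverge(rng, consensus, spec.member_divergence)
        for _ in range(spec.members_per_family)
    ]
    accession = f"PF{index:04d}"
    profile = build_profile(
        members, accession, clan=clan, pseudocount=spec.profile_pseudocount
    )
    return FamilyFixture(
        accession=accession, clan=clan, consensus=consensus, profile=profile
    )


def gen_structure_library(
    rng: np.random.Generator, spec: FixtureSpec, families: Sequence[FamilyFixture]
) -> tuple[StructureLibrary, dict[str, set[str]]]:
    """Family structures (near-consensus reference sequences) plus decoys."""
    entries: list[StructureEntry] = []
    refs: dict[str, str] = {}
    mapping: dict[str, set[str]] = {}
    for fam in families:
        ids = set()
        for s in range(spec.n_structures_per_profile):
            sid = f"d{fam.accession.lower()}{s}"
            ref = diverge(rng, fam.consensus, spec.structure_ref_divergence)
            entries.append(StructureEntry(sid, f"fold_{fam.accession}", len(ref)))
            refs[sid] = ref
            ids.add(sid)
        mapping[fam.accession] = ids
    n_mapped = len(entries)
    if spec.library_size < n_mapped:
        raise ValueError(
            f"library_size {spec.library_size} < {n_mapped} mapped structures"
        )
    lo, hi = spec.profile_length
    for i in range(spec.library_size - n_mapped):
        sid = f"decoy{i:05d}"
        # decoy lengths drawn from the same range as the family domains, so
        # length normalization does not systematically favour family entries
        length = int(rng.integers(lo, hi + 1))
        entries.append(StructureEntry(sid, "decoy_fold", length))
        refs[sid] = random_sequence(rng, length)
    entries.sort(key=lambda e: e.structure_id)
    return StructureLibrary(entries=tuple(entries), reference_sequences=refs), mapping


def gen_background_zscores(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    """Background threading Z-scores; default model is standard normal."""
    return rng.standard_normal(spec.background_z_count)


# ---------------------------------------------------------------------------
# proteome with planted domains and orthologs


def _embed(rng: np.random.Generator, spec: FixtureSpec, member: str) -> tuple[str, int]:
    fl1 = random_sequence(rng, spec.flank_length)
    fl2 = random_sequence(rng, spec.flank_length)
    return fl1 + member + fl2, len(fl1)


def _measure_evalue(
    protein: SequenceRecord,
    accession: str,
    db: Sequence[DomainProfile],
    cfg: SearchConfig,
    ceiling: float,
) -> Optional[float]:
    hits = search_domains(protein, db, cfg, evalue_ceiling=ceiling)
    for h in hits:
        if h.profile_accession == accession:
            return h.evalue
    return None


def _find_hit(
    protein: SequenceRecord,
    accession: str,
    db: Sequence[DomainProfile],
    cfg: SearchConfig,
    ceiling: float,
    region: Optional[tuple[int, int]] = None,
) -> Optional[DomainHit]:
    for h in search_domains(protein, db, cfg, evalue_ceiling=ceiling):
        if h.profile_accession != accession:
            continue
        if region is not None:
            if min(h.env_end, region[1]) - max(h.env_start, region[0]) < 1:
                continue
        return h
    return None


def _fold_accepted(
    protein: SequenceRecord,
    hit: DomainHit,
    library: StructureLibrary,
    structure_map: dict[str, set[str]],
    cdf: EmpiricalCDF,
) -> bool:
    """Mirror of the pipeline's fold-recognition step for one hit."""
    mseq = preprocess_sequence(protein)
    region = extract_domain_region(mseq, hit)
    result = thread(region, library)
    window = top_window(len(library))
    fs = score_threading(result, set(structure_map[hit.profile_accession]), cdf, window)
    return fs.accepted


def _engineer_remote_member(
    rng: np.random.Generator,
    spec: FixtureSpec,
    fam: FamilyFixture,
    db: Sequence[DomainProfile],
    cfg: SearchConfig,
    protein_id: str,
    library: StructureLibrary,
    structure_map: dict[str, set[str]],
    cdf: EmpiricalCDF,
    max_restarts: int = 6,
) -> tuple[SequenceRecord, PlantedDomain]:
    """Plant a member in the remote E-value band with an accepted fold.

    Walks the divergence grid with fresh draws until (a) the in-context
    E-value, measured with the package's own search engine, lands inside
    ``remote_evalue_band`` and (b) the hit region passes fold recognition —
    the engineered guarantees of the fixture.  Deterministic given the
    generator state.
    """
    lo, hi = spec.remote_evalue_band
    fallback = None
    for _ in range(max_restarts):
        for d in spec.remote_divergence_grid:
            member = diverge(rng, fam.consensus, d)
            residues, start = _embed(rng, spec, member)
            protein = SequenceRecord(id=protein_id, residues=residues)
            hit = _find_hit(protein, fam.accession, db, cfg, cfg.report_threshold)
            if hit is None:
                continue
            planted = PlantedDomain(
                protein_id=protein_id,
                accession=fam.accession,
                start=start,
                end=start + len(member),
                divergence=d,
                kind="remote",
                evalue_measured=hit.evalue,
            )
            in_band = lo <= hit.evalue <= hi
            in_remote = cfg.weak_threshold <= hit.evalue <= cfg.report_threshold
            if not (in_band or in_remote):
                continue
            accepted = _fold_accepted(protein, hit, library, structure_map, cdf)
            if in_band and accepted:
                return protein, planted
            if in_remote and accepted and fallback is None:
                fallback = (protein, planted)
    if fallback is not None:
        logger.warning("%s: settled for E=%.3g outside the target band",
                       protein_id, fallback[1].evalue_measured)
        return fallback
    raise RuntimeError(
        f"{protein_id}: could not engineer a remote member for {fam.accession}"
    )


def _engineer_orthologs(
    rng: np.random.Generator,
    spec: FixtureSpec,
    protein: SequenceRecord,
    planted: PlantedDomain,
    db: Sequence[DomainProfile],
    cfg: SearchConfig,
    library: StructureLibrary,
    structure_map: dict[str, set[str]],
    cdf: EmpiricalCDF,
    ortholog_evalue: float = 100.0,
    max_attempts: int = 8,
) -> dict[str, SequenceRecord]:
    """Re-diverged copies per species, verified to re-detect the domain and
    to re-pass fold recognition (the construction behind a passing trio)."""
    out: dict[str, SequenceRecord] = {}
    for species in spec.species:
        oid = f"{protein.id}_{species}"
        chosen = None
        cand = None
        for _ in range(max_attempts):
            residues = diverge(rng, protein.residues, spec.ortholog_divergence)
            cand = SequenceRecord(id=oid, residues=residues)
            hit = _find_hit(
                cand, planted.accession, db, cfg, ortholog_evalue,
                region=(planted.start, planted.end),
            )
            if hit is not None and _fold_accepted(cand, hit, library, structure_map, cdf):
                chosen = cand
                break
        if chosen is None:
            logger.warning("%s: ortholog for %s not re-detectable", oid, species)
            chosen = cand
        out[species] = chosen
    return out


def gen_proteome_with_orthologs(
    rng: np.random.Generator,
    spec: FixtureSpec,
    families: Sequence[FamilyFixture],
    calibrated_db: Sequence[DomainProfile],
    library: StructureLibrary,
    structure_map: dict[str, set[str]],
    cdf: EmpiricalCDF,
    cfg: SearchConfig = SearchConfig(),
) -> tuple[
    list[SequenceRecord],
    dict[str, dict[str, str]],
    dict[str, SequenceRecord],
    list[PlantedDomain],
]:
    """Queries with planted members, ortholog tables, and ground truth.

    Zero-divergence plants are statistically significant by construction;
    remote plants are engineered into the weak E-value band with accepted
    folds, and the first ``n_remote_with_orthologs`` of them receive a
    verified three-species ortholog trio.
    """
    proteome: list[SequenceRecord] = []
    truth: list[PlantedDomain] = []
    ortho_table: dict[str, dict[str, str]] = {}
    ortho_seqs: dict[str, SequenceRecord] = {}

    for i in range(spec.n_significant_proteins):
        fam = families[i % len(families)]
        pid = f"sig{i:03d}"
        residues, start = _embed(rng, spec, fam.consensus)
        proteome.append(SequenceRecord(id=pid, residues=residues))
        truth.append(
            PlantedDomain(
                protein_id=pid,
                accession=fam.accession,
                start=start,
                end=start + len(fam.consensus),
                divergence=0.0,
                kind="significant",
            )
        )

    for i in range(spec.n_remote_proteins):
        fam = families[i % len(families)]
        pid = f"rem{i:03d}"
        protein, planted = _engineer_remote_member(
            rng, spec, fam, calibrated_db, cfg, pid, library, structure_map, cdf
        )
        with_orthologs = i < spec.n_remote_with_orthologs
        if with_orthologs:
            orthologs = _engineer_orthologs(
                rng, spec, protein, planted, calibrated_db, cfg,
                library, structure_map, cdf,
            )
            ortho_table[pid] = {sp: seq.id for sp, seq in orthologs.items()}
            ortho_seqs.update({seq.id: seq for seq in orthologs.values()})
        proteome.append(protein)
        truth.append(replace(planted, has_orthologs=with_orthologs))

    for i in range(spec.n_decoy_proteins):
        pid = f"dec{i:03d}"
        length = int(rng.integers(120, 181))
        proteome.append(SequenceRecord(id=pid, residues=random_sequence(rng, length)))

    return proteome, ortho_table, ortho_seqs, truth


def gen_essential_residues(
    rng: np.random.Generator, spec: FixtureSpec, families: Sequence[FamilyFixture]
) -> dict[str, list[tuple[int, str]]]:
    """Flag a handful of consensus positions per family as essential."""
    out: dict[str, list[tuple[int, str]]] = {}
    for fam in families:
        L = len(fam.consensus)
        k = min(spec.n_essential_positions, L)
        positions = sorted(rng.choice(L, size=k, replace=False).tolist())
        out[fam.accession] = [(p, fam.consensus[p]) for p in positions]
    return out


# ---------------------------------------------------------------------------
# strict / relaxed profile pairs (benchmark fixture)


@dataclass
class StrictRelaxedPair:
    old_profile: DomainProfile  # calibrated
    new_profile: DomainProfile  # calibrated
    far_proteins: list[SequenceRecord]
    far_regions: dict[str, tuple[int, int]]
    qualifying: list[str]  # protein ids measured to satisfy the truth rule
    evalues: dict[str, tuple[float, float]]  # protein id -> (E_old, E_new)


def gen_strict_relaxed_pair(
    rng: np.random.Generator,
    spec: FixtureSpec,
    fam: FamilyFixture,
    n_far: int = 10,
    far_divergence_grid: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90),
    min_qualifying: int = 4,
    cfg: SearchConfig = SearchConfig(),
) -> StrictRelaxedPair:
    """An old (strict) and new (relaxed) release of one family profile.

    The old profile sees only near members; the new one additionally absorbs
    a set of far members, relaxing the family definition.  Each far member is
    embedded in a protein and its E-value against both calibrated releases is
    measured with the package's own search; the qualifying set (old E > 0.1,
    new E < 0.1, >= 10-fold drop) is returned as engineered ground truth.
    The far divergence steps up the grid until enough members qualify.
    """
    near = [diverge(rng, fam.consensus, spec.member_divergence)
            for _ in range(spec.members_per_family)]
    calib_seed = int(rng.integers(2**31 - 1))

    for d_far in far_divergence_grid:
        far = [diverge(rng, fam.consensus, d_far) for _ in range(n_far)]
        old_profile = build_profile(
            near, fam.accession, clan=fam.clan, db_version="old",
            pseudocount=spec.profile_pseudocount,
        )
        new_profile = build_profile(
            near + far, fam.accession, clan=fam.clan, db_version="new",
            pseudocount=spec.profile_pseudocount,
        )
        old_profile = calibrate_profile(old_profile, spec.calibration_n, seed=calib_seed)
        new_profile = calibrate_profile(new_profile, spec.calibration_n, seed=calib_seed + 1)
        far_proteins, far_regions, evalues, qualifying = [], {}, {}, []
        for i, member in enumerate(far):
            pid = f"far{i:03d}"
            residues, start = _embed(rng, spec, member)
            protein = SequenceRecord(id=pid, residues=residues)
            e_old = _measure_evalue(protein, fam.accession, [old_profile], cfg, 1e6)
            e_new = _measure_evalue(protein, fam.accession, [new_profile], cfg, 1e6)
            far_proteins.append(protein)
            far_regions[pid] = (start, start + len(member))
            evalues[pid] = (e_old, e_new)
            if (
                e_old is not None
                and e_new is not None
                and e_old > 0.1
                and e_new < 0.1
                and e_old / e_new >= 10.0
            ):
                qualifying.append(pid)
        if len(qualifying) >= min_qualifying:
            return StrictRelaxedPair(
                old_profile=old_profile,
                new_profile=new_profile,
                far_proteins=far_proteins,
                far_regions=far_regions,
                qualifying=qualifying,
                evalues=evalues,
            )
    logger.warning(
        "strict/relaxed pair: only %d member(s) qualified", len(qualifying)
    )
    return StrictRelaxedPair(
        old_profile=old_profile,
        new_profile=new_profile,
        far_proteins=far_proteins,
        far_regions=far_regions,
        qualifying=qualifying,
        evalues=evalues,
    )


# ---------------------------------------------------------------------------
# the full bundle


def generate_bundle(spec: FixtureSpec = FixtureSpec()) -> FixtureBundle:
    """Everything a pipeline run needs, from one seed."""
    master = np.random.SeedSequence(spec.seed)
    (s_fam, s_lib, s_bg, s_prot, s_cal, s_ess) = master.spawn(6)
    rng_fam = np.random.default_rng(s_fam)
    families = [
        gen_profile_family(rng_fam, spec, i, clan=f"CL{i % 3:03d}")
        for i in range(spec.n_families)
    ]
    cal_seeds = np.random.default_rng(s_cal).integers(2**31 - 1, size=spec.n_families)
    profiles = [
        calibrate_profile(f.profile, spec.calibration_n, seed=int(cal_seeds[i]))
        for i, f in enumerate(families)
    ]
    library, structure_map = gen_structure_library(
        np.random.default_rng(s_lib), spec, families
    )
    background = gen_background_zscores(np.random.default_rng(s_bg), spec)
    cdf = EmpiricalCDF(background, source=f"synthetic-normal seed={spec.seed}")
    proteome, ortho_table, ortho_seqs, truth = gen_proteome_with_orthologs(
        np.random.default_rng(s_prot), spec, families, profiles,
        library, structure_map, cdf,
    )
    essentials = gen_essential_residues(np.random.default_rng(s_ess), spec, families)
    clan_map = {f.accession: f.clan for f in families if f.clan}
    return FixtureBundle(
        spec=spec,
        families=families,
        profiles=profiles,
        library=library,
        structure_map=structure_map,
        clan_map=clan_map,
        background=background,
        cdf=cdf,
        proteome=proteome,
        ortholog_table=ortho_table,
        ortholog_sequences=ortho_seqs,
        essentials=essentials,
        truth=truth,
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> None:
    """Serialize every bundle artifact to the formats the CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.proteome, out / "proteome.fasta")
    write_profiles(bundle.profiles, out / "profiles.tsv")
    write_structure_manifest(bundle.library.entries, out / "structures.tsv")
    write_fasta(
        [
            SequenceRecord(id=sid, residues=seq)
            for sid, seq in sorted(bundle.library.reference_sequences.items())
        ],
        out / "structure_refs.fasta",
    )
    write_structure_map(bundle.structure_map, out / "structure_map.tsv")
    write_clan_map(bundle.clan_map, out / "clans.tsv")
    write_background_zscores(
        bundle.background, out / "background_z.txt", source=bundle.cdf.source
    )
    write_ortholog_table(bundle.ortholog_table, out / "orthologs.tsv")
    write_fasta(
        sorted(bundle.ortholog_sequences.values(), key=lambda r: r.id),
        out / "ortholog_seqs.fasta",
    )
    write_essential_residues(bundle.essentials, out / "essential_residues.tsv")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write(
            "# protein_id\taccession\tstart(1-based)\tend\tdivergence\tkind"
            "\thas_orthologs\tmeasured_evalue\n"
        )
        for t in bundle.truth:
            ev = "-" if t.evalue_measured is None else f"{t.evalue_measured:.4g}"
            fh.write(
                f"{t.protein_id}\t{t.accession}\t{t.start + 1}\t{t.end}\t"
                f"{t.divergence}\t{t.kind}\t{'yes' if t.has_orthologs else 'no'}\t{ev}\n"
            )
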