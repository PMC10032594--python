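"""Synthetic cohorts with known ground truth.

The generator emulates the structure of a large resequenced plant cohort:
~10 subpopulations with hierarchical allele-frequency divergence,
multiallelic diploid STR unit counts under a stepwise mutation model,
block-LD neutral SNPs, environmental variables confounded with population
structure, and per-residue annotation tracks with planted enrichment.  All
downstream stages can therefore be tested for parameter recovery against the
generator's own truth records without any external data.

STR allele model: the subpopulation mean unit count is drawn from a truncated
normal around a global locus mean (scale ``drift_scale``); individual alleles
are the rounded subpopulation mean plus geometric-signed mutation steps,
truncated to [4, 40] units.  Diploid calls draw two alleles independently.

Environment model: a small number of latent factors, each a mixture of a
subpopulation-level component (weight ``confound_strength``) and
accession-level noise; every observed variable loads on one factor plus
independent noise, with geometrically decaying redundancy so the leading
factors dominate the PCA (as leading climatic gradients do).  Planted
genotype-environment effects come in three shapes: ``linear`` shifts allele
unit counts along a latent factor (stochastically rounded so the conditional
mean stays exactly linear); ``threshold`` makes the factor respond to a
genotype step, planting a nonlinear conditional mean; ``cline`` draws a
two-allele mixture whose weight follows the factor logistically, the
canonical signal for allele-frequency/environment scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from strhab.genotypes import MISSING, StrGenotypeMatrix
from strhab.tracts import AnnotationTrackSet, translate_codon

UNIT_MIN, UNIT_MAX = 4, 40

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c1 in "ACGT":
    for _c2 in "ACGT":
        for _c3 in "ACGT":
            _codon = _c1 + _c2 + _c3
            _aa = translate_codon(_codon)
            if _aa != "*":
                _CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth genotype-environment effect at one locus.

    ``beta`` is the unit-count shift per standard deviation of the latent
    environmental factor (linear shape), the step size applied where the
    factor is positive (threshold shape), or the logistic slope of a
    two-allele frequency cline along the factor (cline shape, the canonical
    signal for allele-frequency/environment scans).
    """

    locus_id: str
    env_axis: int
    beta: float
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.shape not in {"linear", "threshold", "cline"}:
            raise ValueError("shape must be 'linear', 'threshold' or 'cline'")


@dataclass
class CohortSpec:
    """Sizes and rates of a synthetic cohort."""

    n_accessions: int = 200
    n_subpops: int = 10
    subpop_sizes: tuple[int, ...] | None = None
    n_str_loci: int = 300
    n_snps: int = 1000
    n_env_vars: int = 88
    drift_scale: float = 1.0
    mutation_geom_p: float = 0.5
    seed: int = 0
    confound_strength: float = 0.5
    n_env_factors: int = 7
    env_noise_sd: float = 0.3
    factor_decay: float = 0.6
    snp_block_size: int = 20
    missing_rate: float = 0.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    n_divergent_loci: int = 0
    divergent_scale: float = 8.0

    def __post_init__(self) -> None:
        if self.subpop_sizes is None:
            base = self.n_accessions // self.n_subpops
            sizes = [base] * self.n_subpops
            for i in range(self.n_accessions - base * self.n_subpops):
                sizes[i] += 1
            self.subpop_sizes = tuple(sizes)
        if sum(self.subpop_sizes) != self.n_accessions:
            raise ValueError("subpop_sizes must sum to n_accessions")
        if len(self.subpop_sizes) != self.n_subpops:
            raise ValueError("subpop_sizes length must equal n_subpops")
        for name in ("n_accessions", "n_subpops", "n_str_loci", "n_snps", "n_env_vars"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.mutation_geom_p <= 1:
            raise ValueError("mutation_geom_p must be in (0, 1]")
        if self.drift_scale < 0:
            raise ValueError("drift_scale must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Everything the generator knows that downstream stages must recover."""

    planted_effects: tuple[PlantedEffect, ...]
    enriched_tracks: dict[str, float]
    subpop_labels: dict[str, str]
    divergent_loci: tuple[str, ...] = ()
    env_factor_scores: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "planted_effects": [asdict(p) for p in self.planted_effects],
            "enriched_tracks": self.enriched_tracks,
            "subpop_labels": self.subpop_labels,
            "divergent_loci": list(self.divergent_loci),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _trunc_normal(rng: np.random.Generator, mean: np.ndarray, sd: float, lo: float, hi: float) -> np.ndarray:
    """Truncated normal draws by resampling (falls back to clipping after 100 rounds)."""
    mean = np.asarray(mean, dtype=float)
    if sd == 0:
        return np.clip(mean.copy(), lo, hi)
    out = rng.normal(mean, sd)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sd)
    return np.clip(out, lo, hi)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[StrGenotypeMatrix, pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate genotypes, SNPs, environment, subpop assignment and truth.

    Returns ``(str_genotypes, snps, env, subpops, truth)``; every output is
    a deterministic function of ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    n, S = spec.n_accessions, spec.n_subpops
    accessions = [f"acc{i:04d}" for i in range(n)]
    subpop_names = [f"pop{k:02d}" for k in range(S)]
    labels = np.repeat(np.arange(S), spec.subpop_sizes)
    subpops = pd.Series([subpop_names[k] for k in labels], index=accessions, name="subpop")

    # --- latent environmental factors (confounded with structure) ----------
    # subpop-level components are orthogonalized so distinct gradients are
    # separable contrasts across subpopulations (what a PCA can recover)
    U = rng.normal(size=(S, spec.n_env_factors))
    if spec.n_env_factors <= S:
        Q, R = np.linalg.qr(U)
        U = Q * np.sign(np.diag(R)) * np.sqrt(S)
    F = np.empty((n, spec.n_env_factors))
    c = spec.confound_strength
    for f in range(spec.n_env_factors):
        F[:, f] = c * U[labels, f] + np.sqrt(max(0.0, 1 - c * c)) * rng.normal(size=n)

    # --- STR genotypes ------------------------------------------------------
    loci = [f"L{j + 1:04d}" for j in range(spec.n_str_loci)]
    planted = {p.locus_id: p for p in spec.planted_effects}
    unknown = set(planted) - set(loci)
    if unknown:
        raise ValueError(f"planted effects refer to unknown loci: {sorted(unknown)}")
    divergent = tuple(loci[j] for j in range(min(spec.n_divergent_loci, spec.n_str_loci)))

    a1 = np.empty((n, spec.n_str_loci), dtype=int)
    a2 = np.empty_like(a1)
    for j, locus in enumerate(loci):
        # reference lengths kept off the 4-unit floor so planted shifts stay
        # in the dynamic range rather than piling up at the truncation bound
        gmean = rng.integers(8, 15)
        if locus in divergent:
            # near-fixed two-allele differences between subpops: the high
            # allele's frequency is U-shaped (Beta(1/s, 1/s)) across subpops
            lo, hi = max(UNIT_MIN, gmean - 3), min(UNIT_MAX, gmean + 3)
            ps = rng.beta(1 / spec.divergent_scale, 1 / spec.divergent_scale, size=S)
            for arr in (a1, a2):
                arr[:, j] = np.where(rng.uniform(size=n) < ps[labels], hi, lo)
            continue
        if locus in planted and planted[locus].shape == "cline":
            p = planted[locus]
            lo, hi = max(UNIT_MIN, gmean - 3), min(UNIT_MAX, gmean + 3)
            prob = 1 / (1 + np.exp(-p.beta * F[:, p.env_axis]))
            for arr in (a1, a2):
                arr[:, j] = np.where(rng.uniform(size=n) < prob, hi, lo)
            continue
        mu = _trunc_normal(rng, np.full(S, float(gmean)), spec.drift_scale, UNIT_MIN, UNIT_MAX)
        base = np.rint(mu[labels]).astype(int)
        for arr in (a1, a2):
            steps = rng.geometric(spec.mutation_geom_p, size=n) - 1
            signs = rng.choice([-1, 1], size=n)
            arr[:, j] = base + signs * steps
        if locus in planted and planted[locus].shape == "linear":
            # unit counts shift linearly along the latent axis; stochastic
            # rounding keeps the conditional mean exactly linear
            p = planted[locus]
            shift = p.beta * F[:, p.env_axis]
            for arr in (a1, a2):
                arr[:, j] += np.floor(shift + rng.uniform(size=n)).astype(int)
        np.clip(a1[:, j], UNIT_MIN, UNIT_MAX, out=a1[:, j])
        np.clip(a2[:, j], UNIT_MIN, UNIT_MAX, out=a2[:, j])

    # threshold effects act forward: the latent factor responds to a genotype
    # threshold, planting a step-shaped (nonlinear) conditional mean over the
    # overlapping multiallelic support that a linear fit cannot absorb
    for locus, p in planted.items():
        if p.shape != "threshold":
            continue
        j = loci.index(locus)
        dipsum = a1[:, j] + a2[:, j]
        F[:, p.env_axis] += p.beta * (dipsum > np.median(dipsum))

    # --- observed environmental variables ----------------------------------
    env = np.empty((n, spec.n_env_vars))
    var_names = [f"env{j + 1:03d}" for j in range(spec.n_env_vars)]
    # redundancy hierarchy: leading factors collect geometrically more
    # variables (as leading climatic gradients do), so the axes of the
    # standardized PCA align stably with the factors
    strength = spec.factor_decay ** np.arange(spec.n_env_factors)
    weights = strength / strength.sum()
    counts = np.maximum(1, np.round(weights * spec.n_env_vars).astype(int))
    factor_of_var = np.repeat(np.arange(spec.n_env_factors), counts)[: spec.n_env_vars]
    if factor_of_var.size < spec.n_env_vars:
        factor_of_var = np.concatenate(
            [factor_of_var, np.zeros(spec.n_env_vars - factor_of_var.size, dtype=int)]
        )
    for j in range(spec.n_env_vars):
        f = int(factor_of_var[j])
        loading = rng.uniform(0.7, 1.3) * rng.choice([-1.0, 1.0]) * strength[f]
        env[:, j] = loading * F[:, f] + spec.env_noise_sd * rng.normal(size=n)
    env_df = pd.DataFrame(env, index=accessions, columns=var_names)

    if spec.missing_rate > 0:
        mask = rng.uniform(size=a1.shape) < spec.missing_rate
        a1[mask] = MISSING
        a2[mask] = MISSING
    geno = StrGenotypeMatrix(accessions, loci, a1, a2)

    # --- block-LD neutral SNPs ----------------------------------------------
    theta = min(0.5, 0.1 * spec.drift_scale)
    snp = np.empty((n, spec.n_snps), dtype=np.int8)
    b = spec.snp_block_size
    for start in range(0, spec.n_snps, b):
        width = min(b, spec.n_snps - start)
        p0 = rng.uniform(0.1, 0.9)
        if theta > 0:
            a_par = p0 * (1 - theta) / theta
            b_par = (1 - p0) * (1 - theta) / theta
            ps = rng.beta(a_par, b_par, size=S)
        else:
            ps = np.full(S, p0)
        anchor = rng.uniform(size=(n, 2)) < ps[labels][:, None]  # two haplotypes
        flip = rng.uniform(0.02, 0.25, size=width)
        for w in range(width):
            flips = rng.uniform(size=(n, 2)) < flip[w]
            hap = anchor ^ flips
            snp[:, start + w] = hap.sum(axis=1)
    snp_df = pd.DataFrame(snp, index=accessions, columns=[f"snp{j + 1:05d}" for j in range(spec.n_snps)])

    truth = SyntheticTruth(
        planted_effects=spec.planted_effects,
        enriched_tracks={},
        subpop_labels={a: subpops[a] for a in accessions},
        divergent_loci=divergent,
        env_factor_scores=pd.DataFrame(
            F, index=accessions, columns=[f"factor{f}" for f in range(spec.n_env_factors)]
        ),
    )
    return geno, snp_df, env_df, subpops, truth


# ---------------------------------------------------------------------------
# CDS sequences with embedded tracts


def generate_cds_with_tracts(
    n_proteins: int,
    tract_spec: Sequence[tuple[str, int]],
    seed: int = 0,
    flank_codons: int = 10,
) -> tuple[dict[str, str], pd.DataFrame]:
    """CDS sequences with in-frame trinucleotide repeats at known coordinates.

    ``tract_spec`` lists (amino_acid, unit_count) tracts; tract ``i`` is
    embedded in protein ``i % n_proteins``, so a protein may carry several
    tracts separated by repeat-free flanks.  Flanks never contain two
    consecutive identical amino acids, so no spurious tract of >= 2 units can
    arise outside the embedded ones.  The truth table records every embedded
    tract (also those below the 4-unit detection floor, flagged
    ``detectable=False``).
    """
    rng = np.random.default_rng(seed)
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    aa_pool = sorted(set(_CODONS_BY_AA) - {"M", "W"})
    for aa, units in tract_spec:
        if aa not in _CODONS_BY_AA:
            raise ValueError(f"invalid amino acid {aa!r}")
        if units < 1:
            raise ValueError("unit_count must be >= 1")

    per_protein: dict[int, list[tuple[str, int]]] = {i: [] for i in range(n_proteins)}
    for i, ts in enumerate(tract_spec):
        per_protein[i % n_proteins].append(ts)

    def flank(n_codons: int, avoid: set[str]) -> list[str]:
        out: list[str] = []
        prev = None
        for _ in range(n_codons):
            choices = [a for a in aa_pool if a != prev and a not in avoid]
            aa = choices[rng.integers(len(choices))]
            out.append(_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))])
            prev = aa
        return out

    seqs: dict[str, str] = {}
    rows = []
    for i in range(n_proteins):
        pid = f"prot{i + 1:04d}"
        codons: list[str] = ["ATG"]
        for aa, units in per_protein[i]:
            codons += flank(flank_codons, avoid={aa})
            start = len(codons)
            codon = _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
            codons += [codon] * units
            rows.append(
                {
                    "protein_id": pid,
                    "locus_id": f"{pid}:{3 * start}:{aa}",
                    "amino_acid": aa,
                    "unit_count": units,
                    "cds_start": 3 * start,
                    "cds_end": 3 * (start + units),
                    "protein_start": start + 1,
                    "protein_end": start + units,
                    "detectable": units >= 4,
                }
            )
            # guard codon differing from the tract amino acid
            codons += flank(1, avoid={aa})
        codons += flank(flank_codons, avoid=set())
        codons.append("TGA")
        seqs[pid] = "".join(codons)
    truth = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "locus_id",
            "amino_acid",
            "unit_count",
            "cds_start",
            "cds_end",
            "protein_start",
            "protein_end",
            "detectable",
        ],
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# annotation tracks with planted enrichment


# per-residue inclusion rates; kept sparse so that the tract-level overlap
# fractions (>=1 shared residue over a 5-11 residue tract) stay moderate
DEFAULT_BACKGROUND = {
    "idr": 0.05,
    "ppi_1": 0.03,
    "ppi_2": 0.03,
    "ppi_3": 0.03,
    "dpi": 0.02,
    "rpi": 0.02,
}


def generate_annotation_tracks(
    proteins: Mapping[str, tuple[int, set[int]]],
    enrichment: Mapping[str, float],
    seed: int = 0,
    background: Mapping[str, float] | None = None,
) -> tuple[AnnotationTrackSet, dict[str, float]]:
    """Binary residue tracks with tract residues included at inflated odds.

    ``proteins`` maps protein id -> (length, tract residue set, 1-based).
    ``enrichment`` maps track name ('idr', 'ppi_1'..'ppi_3', 'dpi', 'rpi')
    to a planted log odds ratio; a residue inside a tract is included with
    probability sigma(logit(p0) + logOR) where p0 is the track's background
    rate.  Returns the track set and the planted per-track log ORs actually
    used (0.0 where unspecified).
    """
    rng = np.random.default_rng(seed)
    bg = dict(DEFAULT_BACKGROUND)
    if background:
        bg.update(background)
    for name, lor in enrichment.items():
        if name not in bg:
            raise ValueError(f"unknown track {name!r}")
        if not np.isfinite(lor):
            raise ValueError("planted log odds ratios must be finite")
    for name, p0 in bg.items():
        if not 0 < p0 < 1:
            raise ValueError(f"background rate for {name} must be in (0, 1)")

    tracks = AnnotationTrackSet()
    planted = {name: float(enrichment.get(name, 0.0)) for name in bg}
    named = tracks.named_tracks()
    for pid, (length, tract_res) in proteins.items():
        tracks.protein_lengths[pid] = length
        in_tract = np.zeros(length + 1, dtype=bool)
        for r in tract_res:
            if not 1 <= r <= length:
                raise ValueError(f"tract residue {r} outside protein {pid} (length {length})")
            in_tract[r] = True
        for name, track in named.items():
            p0 = bg[name]
            logit = np.log(p0 / (1 - p0)) + planted[name]
            p1 = 1 / (1 + np.exp(-logit))
            u = rng.uniform(size=length + 1)
            prob = np.where(in_tract, p1, p0)
            hit = u < prob
            hit[0] = False
            track[pid] = set(np.flatnonzero(hit).tolist())
    return tracks, planted


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class StudyBundle:
    """All inputs of one synthetic study, keyed consistently by locus id."""

    spec: CohortSpec
    geno: StrGenotypeMatrix
    snps: pd.DataFrame
    env: pd.DataFrame
    subpops: pd.Series
    truth: SyntheticTruth
    cds: dict[str, str]
    tract_truth: pd.DataFrame
    tracks: AnnotationTrackSet
    locus_aa: pd.Series  # locus -> amino acid
    locus_protein: pd.Series  # locus -> protein id


def generate_study(
    spec: CohortSpec,
    aa_weights: Mapping[str, float] | None = None,
    enrichment: Mapping[str, float] | None = None,
    effect_rule: Callable[[str, bool], PlantedEffect | None] | None = None,
    track_background: Mapping[str, float] | None = None,
) -> StudyBundle:
    """One coherent synthetic study: cohort + proteome + annotation tracks.

    Each STR locus corresponds to one homopolymer tract embedded in its own
    protein.  Amino acids are drawn from ``aa_weights`` (uniform over a polar
    and charged palette by default).  If ``effect_rule`` is given it is called
    per locus with (amino_acid, in_disorder) and may return a
    :class:`PlantedEffect` template (its ``locus_id`` is ignored and replaced),
    allowing feature-dependent planted effects for end-to-end recovery tests.
    """
    rng = np.random.default_rng(spec.seed + 1)
    palette = aa_weights or {aa: 1.0 for aa in "QNSTDEAGHPK"}
    aas = sorted(palette)
    w = np.array([palette[a] for a in aas], dtype=float)
    w /= w.sum()
    n_loci = spec.n_str_loci
    locus_ids = [f"L{j + 1:04d}" for j in range(n_loci)]
    aa_choice = rng.choice(aas, size=n_loci, p=w)
    ref_units = rng.integers(5, 12, size=n_loci)

    cds, tract_truth = generate_cds_with_tracts(
        n_proteins=n_loci,
        tract_spec=[(aa, int(u)) for aa, u in zip(aa_choice, ref_units)],
        seed=spec.seed + 2,
    )
    tract_truth = tract_truth.copy()
    tract_truth["cohort_locus"] = locus_ids

    proteins = {}
    for _, row in tract_truth.iterrows():
        pid = row["protein_id"]
        length = len(cds[pid]) // 3 - 1  # minus stop
        res = set(range(row["protein_start"], row["protein_end"] + 1))
        proteins[pid] = (length, proteins.get(pid, (length, set()))[1] | res)

    tracks, planted_or = generate_annotation_tracks(
        proteins, enrichment or {}, seed=spec.seed + 3, background=track_background
    )

    # feature-dependent planted effects need disorder state, so compute overlap
    in_disorder = {}
    for _, row in tract_truth.iterrows():
        res = set(range(row["protein_start"], row["protein_end"] + 1))
        idr = tracks.idr.get(row["protein_id"], set())
        in_disorder[row["cohort_locus"]] = len(res & idr) >= 1

    effects = list(spec.planted_effects)
    if effect_rule is not None:
        for locus, aa in zip(locus_ids, aa_choice):
            eff = effect_rule(aa, in_disorder[locus])
            if eff is not None:
                effects.append(
                    PlantedEffect(locus_id=locus, env_axis=eff.env_axis, beta=eff.beta, shape=eff.shape)
                )
    spec2 = CohortSpec(**{**asdict_spec(spec), "planted_effects": tuple(effects)})
    geno, snps, env, subpops, truth = generate_cohort(spec2)
    truth.enriched_tracks = planted_or

    return StudyBundle(
        spec=spec2,
        geno=geno,
        snps=snps,
        env=env,
        subpops=subpops,
        truth=truth,
        cds=cds,
        tract_truth=tract_truth,
        tracks=tracks,
        locus_aa=pd.Series(aa_choice, index=locus_ids, name="amino_acid"),
        locus_protein=pd.Series(tract_truth["protein_id"].to_numpy(), index=locus_ids, name="protein_id"),
    )


def asdict_spec(spec: CohortSpec) -> dict:
    """Field dict of a CohortSpec with nested planted effects preserved."""
    d = {f: getattr(spec, f) for f in spec.__dataclass_fields__}
    return d


def study_feature_vectors(bundle: StudyBundle):
    """Tract feature vectors for a study bundle, keyed by cohort locus id."""
    from strhab.tracts import HomopolymerTract, intersect_tracts

    tracts = []
    for _, row in bundle.tract_truth.iterrows():
        unit = bundle.cds[row["protein_id"]][row["cds_start"] : row["cds_start"] + 3]
        tracts.append(
            HomopolymerTract(
                locus_id=row["cohort_locus"],
                transcript_id=row["protein_id"],
                amino_acid=row["amino_acid"],
                unit_count=int(row["unit_count"]),
                cds_interval=(int(row["cds_start"]), int(row["cds_end"])),
                protein_interval=(int(row["protein_start"]), int(row["protein_end"])),
                repeat_unit=unit,
            )
        )
    return intersect_tracts(tracts, bundle.tracks)
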