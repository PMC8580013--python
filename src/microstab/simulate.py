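"""Synthetic two-cohort longitudinal vaginal-microbiome study generator.

Emulates a gynecologic-cancer vs. healthy postmenopausal cohort sampled at
four timepoints (baseline T0, then ~3, 6 and 12 months), with

* seven vaginal community types (CTs) of stated character — a
  Lactobacillus-dominated type, Gardnerella/Atopobium, Streptococcus- and
  Bifidobacterium-marked types, a diffuse high-diversity anaerobe type and
  two Prevotella types split by their companion anaerobes;
* cohort-dependent community turnover: each subject follows a
  uniform-restart Markov chain over CTs whose per-interval switch
  probability depends on cohort, so cancer subjects drift between
  community types more often and end up with larger within-subject
  Bray-Curtis dissimilarities;
* sequencing depth lognormal around a median of 35,200 reads;
* contaminated low-yield blanks (total reads below 3,200) populated with
  the classic reagent contaminants;
* symptoms statistically tied to the community: vaginal dryness
  probability decreases logistically in log Lactobacillus relative
  abundance, and pH increases as Lactobacillus is lost.

Everything is driven by one integer seed; regenerating with the same
config is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim

from microstab.tables import GenusCountTable, MetadataTable

# --------------------------------------------------------------------------
# default community-type templates
# --------------------------------------------------------------------------

#: the diffuse anaerobes backing the high-diversity type
_DIVERSE_ANAEROBES = [
    "Dialister",
    "Megasphaera",
    "Peptostreptococcus",
    "Mobiluncus",
    "Finegoldia",
    "Parvimonas",
    "Gemella",
    "Actinomyces",
    "Aerococcus",
    "Ureaplasma",
    "Campylobacter",
    "Eggerthella",
]

GENUS_PANEL = [
    "Lactobacillus",
    "Gardnerella",
    "Atopobium",
    "Streptococcus",
    "Bifidobacterium",
    "Prevotella",
    "Sneathia",
    "Veillonella",
    "Porphyromonas",
    "Peptoniphilus",
    "Fusobacterium",
    "Anaerococcus",
] + _DIVERSE_ANAEROBES

DEFAULT_CONTAMINANTS = [
    "Escherichia",
    "Stenotrophomonas",
    "Ralstonia",
    "Corynebacterium",
]


def _profile(weights: dict[str, float], floor: float = 0.002) -> dict[str, float]:
    """Mean-proportion vector over the genus panel, with a small floor on
    every panel genus so Dirichlet concentrations stay positive."""
    p = {g: floor for g in GENUS_PANEL}
    for g, w in weights.items():
        p[g] += w
    tot = sum(p.values())
    return {g: v / tot for g, v in p.items()}


def default_ct_profiles() -> dict[str, dict[str, float]]:
    """Seven CT templates mirroring the study's qualitative descriptions.

    CT-A Lactobacillus-dominated (~95%); CT-B Gardnerella+Atopobium without
    Prevotella; CT-C Streptococcus >40%; CT-D Bifidobacterium ~25%; CT-E
    twelve diffuse anaerobes with no dominant taxon; CT-F Prevotella with
    Atopobium/Sneathia/Veillonella/Gardnerella; CT-G Prevotella with
    Porphyromonas/Peptoniphilus/Fusobacterium/Anaerococcus.
    """
    return {
        "CT-A": _profile({"Lactobacillus": 0.95}),
        "CT-B": _profile(
            {"Gardnerella": 0.45, "Atopobium": 0.30, "Lactobacillus": 0.10,
             "Veillonella": 0.05}
        ),
        "CT-C": _profile(
            {"Streptococcus": 0.50, "Lactobacillus": 0.15, "Gardnerella": 0.10,
             "Anaerococcus": 0.10}
        ),
        "CT-D": _profile(
            {"Bifidobacterium": 0.30, "Lactobacillus": 0.20, "Gardnerella": 0.15,
             "Streptococcus": 0.10, "Atopobium": 0.10}
        ),
        "CT-E": _profile({g: 0.98 / len(_DIVERSE_ANAEROBES) for g in _DIVERSE_ANAEROBES}),
        "CT-F": _profile(
            {"Prevotella": 0.35, "Atopobium": 0.15, "Sneathia": 0.13,
             "Veillonella": 0.12, "Gardnerella": 0.12}
        ),
        "CT-G": _profile(
            {"Prevotella": 0.30, "Porphyromonas": 0.16, "Peptoniphilus": 0.14,
             "Fusobacterium": 0.14, "Anaerococcus": 0.13}
        ),
    }


#: baseline CT prevalence weights used to draw each subject's initial type,
#: shaped like the observed CT shares (Lactobacillus type most prevalent)
DEFAULT_CT_WEIGHTS = {
    "cancer": {"CT-A": 0.17, "CT-B": 0.10, "CT-C": 0.06, "CT-D": 0.06,
               "CT-E": 0.15, "CT-F": 0.21, "CT-G": 0.25},
    "healthy": {"CT-A": 0.40, "CT-B": 0.12, "CT-C": 0.05, "CT-D": 0.07,
                "CT-E": 0.05, "CT-F": 0.18, "CT-G": 0.13},
}

#: cohort-specific per-symptom baseline presence probabilities
DEFAULT_SYMPTOM_BASELINES = {
    "cancer": {
        "ctcae_dyspareunia": 0.30, "ctcae_vaginal_pain": 0.40,
        "ctcae_dryness": 0.16, "ctcae_hemorrhage": 0.30,
        "ctcae_inflammation": 0.30, "ctcae_vaginismus": 0.25,
        "pro_itching": 0.20, "pro_discharge": 0.25, "pro_bleeding": 0.25,
    },
    "healthy": {
        "ctcae_dyspareunia": 0.20, "ctcae_vaginal_pain": 0.10,
        "ctcae_dryness": 0.45, "ctcae_hemorrhage": 0.05,
        "ctcae_inflammation": 0.08, "ctcae_vaginismus": 0.03,
        "pro_itching": 0.15, "pro_discharge": 0.15, "pro_bleeding": 0.05,
    },
}


@dataclass
class SimConfig:
    """Study-generator configuration.

    The defaults encode the study conditions: 25 cancer / 27 healthy
    subjects with full four-timepoint series, median sample depth 35,200
    reads, blanks capped below 3,200 reads, and a cancer switch probability
    of 0.6 per interval against 0.2 for healthy subjects.
    """

    n_cancer: int = 25
    n_healthy: int = 27
    n_timepoints: int = 4
    depth_median: int = 35200
    depth_dispersion: float = 0.35  # log-scale sd of the lognormal depth
    ct_profiles: dict[str, dict[str, float]] = field(default_factory=default_ct_profiles)
    ct_concentration: float = 120.0  # Dirichlet concentration (sum of alphas)
    ct_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(w) for c, w in DEFAULT_CT_WEIGHTS.items()}
    )
    transition: dict[str, float] = field(
        default_factory=lambda: {"cancer": 0.6, "healthy": 0.2}
    )
    # logistic model for dryness: logit P = intercept + slope * log10(lacto + eps)
    dryness_intercept: float = -3.2
    dryness_slope: float = -1.1
    ph_base: float = 4.3
    ph_lacto_effect: float = 2.2  # pH rise from full Lactobacillus loss
    ph_sd: float = 0.35
    symptom_baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_SYMPTOM_BASELINES.items()}
    )
    n_blanks: int = 8
    blank_depth_max: int = 3200
    contaminant_genera: list[str] = field(default_factory=lambda: list(DEFAULT_CONTAMINANTS))
    pseudocount: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.depth_median <= 0:
            raise ValueError("depth_median must be positive")
        if self.blank_depth_max <= 0:
            raise ValueError("blank_depth_max must be positive")
        for cohort, p in self.transition.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"transition[{cohort!r}]={p} outside [0,1]")
        for label, prof in self.ct_profiles.items():
            s = sum(prof.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"ct_profile {label!r} sums to {s}, not 1")
            if any(v < 0 for v in prof.values()):
                raise ValueError(f"ct_profile {label!r} has negative entries")

    # -- YAML round trip --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class SyntheticStudy:
    """A complete generated study."""

    counts: GenusCountTable
    blanks: GenusCountTable
    tree: str  # newick text
    metadata: MetadataTable
    symptoms: pd.DataFrame
    truth: dict  # per-subject cohort and planted CT sequence

    def write(self, outdir: str | Path) -> None:
        from microstab import tables

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables.write_count_table(self.counts, outdir / "counts.tsv")
        tables.write_count_table(self.blanks, outdir / "blanks.tsv")
        (outdir / "tree.nwk").write_text(self.tree)
        tables.write_metadata(self.metadata, outdir / "metadata.csv")
        tables.write_symptoms(self.symptoms, outdir / "symptoms.csv")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


# --------------------------------------------------------------------------
# core draws
# --------------------------------------------------------------------------

def sample_community(
    ct_label: str, depth: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one genus count vector around a CT template.

    Dirichlet-multinomial: proportions ~ Dirichlet(concentration x profile),
    counts ~ Multinomial(depth, proportions). Returns counts ordered as
    ``GENUS_PANEL`` restricted to the profile's genera (config profile order).
    """
    if ct_label not in config.ct_profiles:
        raise KeyError(f"unknown community type {ct_label!r}")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    profile = config.ct_profiles[ct_label]
    mean = np.array(list(profile.values()), dtype=float)
    alpha = config.ct_concentration * mean
    p = rng.dirichlet(alpha)
    return rng.multinomial(int(depth), p)


def evolve_subject(
    cohort: str,
    initial_ct: str,
    n_timepoints: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[str]:
    """Uniform-restart Markov chain over community types.

    At each interval the subject keeps its CT with probability
    ``1 - transition[cohort]``; on a switch, the new CT is uniform over the
    remaining types.
    """
    if cohort not in config.transition:
        raise KeyError(f"no transition probability for cohort {cohort!r}")
    labels = list(config.ct_profiles)
    seq = [initial_ct]
    p_switch = config.transition[cohort]
    for _ in range(n_timepoints - 1):
        if rng.random() < p_switch:
            others = [c for c in labels if c != seq[-1]]
            seq.append(others[rng.integers(len(others))])
        else:
            seq.append(seq[-1])
    return seq


def dryness_probability(lacto_prop: float, config: SimConfig) -> float:
    """Planted logistic link: P(dryness) falls with Lactobacillus abundance."""
    x = np.log10(lacto_prop + config.pseudocount)
    logit = config.dryness_intercept + config.dryness_slope * x
    return float(1.0 / (1.0 + np.exp(-logit)))


def generate_symptoms(
    composition: np.ndarray | dict[str, float],
    cohort: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Draw one sample's symptom grades, FSFI domains and pH.

    ``composition`` is a relative-abundance vector over ``GENUS_PANEL``
    order (or a genus->proportion mapping). Dryness (both the clinician
    grade and the patient-reported grade) follows the planted logistic
    decreasing in Lactobacillus; pH rises as Lactobacillus is lost; the
    remaining symptoms are cohort-baseline Bernoulli draws with a random
    severity grade when present.
    """
    if isinstance(composition, dict):
        comp = composition
    else:
        comp = dict(zip(GENUS_PANEL, np.asarray(composition, dtype=float)))
    total = sum(comp.values())
    if not np.isclose(total, 1.0, atol=1e-3):
        raise ValueError(f"composition sums to {total:.4f}, expected ~1")
    lacto = comp.get("Lactobacillus", 0.0)

    p_dry = dryness_probability(lacto, config)
    baselines = config.symptom_baselines[cohort]
    out: dict[str, float] = {}
    # clinician CTCAE grades, 0-3
    for name in ["ctcae_dyspareunia", "ctcae_vaginal_pain", "ctcae_dryness",
                 "ctcae_hemorrhage", "ctcae_inflammation", "ctcae_vaginismus"]:
        p = p_dry if name == "ctcae_dryness" else baselines[name]
        present = rng.random() < p
        out[name] = int(rng.integers(1, 4)) if present else 0
    # patient-reported PRO-CTCAE grades, 0-4
    for name in ["pro_dryness", "pro_itching", "pro_discharge", "pro_bleeding"]:
        p = p_dry if name == "pro_dryness" else baselines[name]
        present = rng.random() < p
        out[name] = int(rng.integers(1, 5)) if present else 0
    # FSFI domains 0-6; worse function (lower score) when Lactobacillus low
    shift = 1.5 * (1.0 - lacto)
    for dom in ["desire", "arousal", "lubrication", "orgasm", "satisfaction", "pain"]:
        score = np.clip(rng.normal(5.0 - shift, 0.8), 0.0, 6.0)
        out[f"fsfi_{dom}"] = round(float(score), 1)
    out["fsfi_composite"] = round(
        sum(out[f"fsfi_{d}"] for d in
            ["desire", "arousal", "lubrication", "orgasm", "satisfaction", "pain"]), 1
    )
    ph = config.ph_base + config.ph_lacto_effect * (1.0 - lacto) + rng.normal(0, config.ph_sd)
    out["pH"] = round(float(np.clip(ph, 4.0, 7.7)), 1)
    return out


# --------------------------------------------------------------------------
# tree
# --------------------------------------------------------------------------

def simulate_genus_tree(genera: list[str], seed: int) -> str:
    """Random Kingman coalescent over the genera, branch lengths rescaled
    to unit mean; returned as newick text."""
    tns = dendropy.TaxonNamespace(list(genera))
    tree = treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(int(seed))
    )
    lengths = [e.length for e in tree.edges() if e.length]
    mean_len = float(np.mean(lengths))
    for e in tree.edges():
        if e.length is not None:
            e.length = e.length / mean_len
    return tree.as_string(schema="newick", suppress_rooting=True)


# --------------------------------------------------------------------------
# full cohort
# --------------------------------------------------------------------------

def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    labels = list(weights)
    w = np.array([weights[c] for c in labels], dtype=float)
    return labels[rng.choice(len(labels), p=w / w.sum())]


def generate_cohort(config: SimConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study (counts, blanks, tree, metadata,
    symptoms, planted truth), reproducibly from ``config.seed``."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    timepoints = [f"T{t}" for t in range(config.n_timepoints)]
    genera = list(GENUS_PANEL)
    all_genera = genera + [g for g in config.contaminant_genera if g not in genera]

    subjects = [(f"C{i + 1:02d}", "cancer") for i in range(config.n_cancer)]
    subjects += [(f"H{i + 1:02d}", "healthy") for i in range(config.n_healthy)]

    count_cols: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    sym_rows: list[dict] = []
    truth: dict[str, dict] = {}

    for subject, cohort in subjects:
        initial = _weighted_choice(rng, config.ct_weights[cohort])
        ct_seq = evolve_subject(cohort, initial, config.n_timepoints, config, rng)
        truth[subject] = {"cohort": cohort, "ct_sequence": ct_seq}
        # subject-level covariates held fixed across timepoints
        age = round(float(rng.normal(57.5 if cohort == "cancer" else 60.0, 10.0)), 1)
        bmi = round(float(rng.normal(29.0, 7.5)), 1)
        race = _weighted_choice(
            rng, {"Caucasian": 0.60, "AfricanAmerican": 0.35, "Asian": 0.05}
        )
        surgery = bool(rng.random() < 0.57) if cohort == "cancer" else False
        chemo = bool(rng.random() < 0.33) if cohort == "cancer" else False
        for tp, ct in zip(timepoints, ct_seq):
            sid = f"{subject}_{tp}"
            depth = int(round(rng.lognormal(np.log(config.depth_median),
                                            config.depth_dispersion)))
            depth = max(depth, 1)
            vec = sample_community(ct, depth, config, rng)
            profile_genera = list(config.ct_profiles[ct])
            col = np.zeros(len(all_genera), dtype=np.int64)
            for g, c in zip(profile_genera, vec):
                col[all_genera.index(g)] = c
            count_cols[sid] = col
            comp = {g: c / depth for g, c in zip(profile_genera, vec)}
            sym = generate_symptoms(comp, cohort, config, rng)
            radiation = cohort == "cancer" and tp != "T0"
            meta_rows.append({
                "sample": sid, "subject": subject, "cohort": cohort,
                "timepoint": tp, "age": age, "BMI": bmi, "race": race,
                "pH": sym["pH"],
                "antibiotics_4w": bool(rng.random() < 0.10),
                "estrogen_4w": bool(rng.random() < (0.35 if cohort == "healthy" else 0.20)),
                "HRT_4w": bool(rng.random() < 0.15),
                "douching_4w": bool(rng.random() < 0.05),
                "lubricant_4w": bool(rng.random() < 0.25),
                "probiotics_4w": bool(rng.random() < 0.10),
                "intercourse_4w": bool(rng.random() < 0.40),
                "surgery": surgery, "chemo": chemo, "radiation": radiation,
            })
            sym_rows.append({"sample": sid, "subject": subject,
                             "timepoint": tp, **sym})

    # blanks: low-yield, contaminant-dominated
    blank_cols: dict[str, np.ndarray] = {}
    contam = [g for g in config.contaminant_genera]
    for k in range(config.n_blanks):
        depth = int(rng.integers(100, config.blank_depth_max))
        p = rng.dirichlet(np.full(len(contam), 0.8))
        vec = rng.multinomial(depth, p)
        col = np.zeros(len(all_genera), dtype=np.int64)
        for g, c in zip(contam, vec):
            col[all_genera.index(g)] = c
        blank_cols[f"BLANK_{k + 1}"] = col

    counts = GenusCountTable(pd.DataFrame(count_cols, index=all_genera))
    blanks = GenusCountTable(pd.DataFrame(blank_cols, index=all_genera))
    meta = pd.DataFrame(meta_rows).set_index("sample")
    symptoms = pd.DataFrame(sym_rows).set_index("sample")
    tree = simulate_genus_tree(all_genera, seed=int(config.seed) + 1)
    return SyntheticStudy(
        counts=counts,
        blanks=blanks,
        tree=tree,
        metadata=MetadataTable(meta),
        symptoms=symptoms,
        truth=truth,
    )
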