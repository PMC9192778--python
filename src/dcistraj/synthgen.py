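"""Synthetic ductal-lesion cohorts with known ground truth.

The generator emulates the statistical structure of a large micro-dissected
breast-lesion RNA-seq cohort: ~145 patients contributing 1-30 lesions each,
every lesion cut into 1-3 adjacent replicate sections (one RNA-seq library
per section), five tissue types (normal, benign, atypia, DCIS, IDC), and a
latent progression coordinate ``t`` in [0, 1] shared by the sections of a
lesion. Expression programs are driven by ``t``:

* a basal/epithelial-integrity program whose mean declines monotonically
  in ``t`` (progressive loss of the basal layer toward invasion);
* an EMT program with two peaks, one early (t ~ 0.25) and one late
  (t ~ 0.9) at the convergence of DCIS and IDC profiles;
* a proliferation program switched on just after the first EMT peak;
* outcome-linked marker genes (CAMK2N1, MNX1, HOXC11, ANKRD22, ADCY5,
  SCGB2A1, THRSP, HOXC10) whose bimodality comes from a patient-level
  low/high state with state probabilities depending on whether the patient
  is "Pure DCIS" (never diagnosed with IDC) or "Not Pure";
* receptor transcripts (ESR1, PGR, ERBB2) bimodal by receptor status.

Counts are negative binomial around library-size-scaled program means, with
a per-patient, per-gene log-normal random effect providing the strong
inter-patient heterogeneity the downstream patient-blocked statistics
assume. Patient outcome (Pure vs Not Pure) is independent of ``t`` by
construction: lesion position on the progression axis does not by itself
encode the patient's diagnosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TISSUES = ("normal", "benign", "atypia", "DCIS", "IDC")
# lesion tissue-type mixes conditional on patient category; patients whose
# biopsy contains IDC draw from the second row, all others from the first
TISSUE_MIX_NO_IDC = {"normal": 0.08, "benign": 0.09, "atypia": 0.10, "DCIS": 0.73, "IDC": 0.0}
TISSUE_MIX_WITH_IDC = {"normal": 0.05, "benign": 0.06, "atypia": 0.07, "DCIS": 0.42, "IDC": 0.40}
# latent-t bands per tissue: normal/benign low, IDC high, DCIS spanning
TISSUE_T_BANDS = {
    "normal": (0.0, 0.10),
    "benign": (0.02, 0.18),
    "atypia": (0.12, 0.35),
    "DCIS": (0.15, 0.85),
    "IDC": (0.70, 1.0),
}

MARKER_GENES = ("CAMK2N1", "MNX1", "HOXC11", "ANKRD22", "ADCY5", "SCGB2A1", "THRSP", "HOXC10")
# direction of the IDC-associated state: "low" = reduced in Not-Pure patients
MARKER_DIRECTIONS = {g: "low" for g in MARKER_GENES} | {"SCGB2A1": "high"}
RECEPTOR_GENES = ("ESR1", "PGR", "ERBB2")

PROGRAM_LABELS = ("basal", "emt", "proliferation", "marker", "receptor", "background")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the cohort scale of the motivating study: ~145 patients,
    a right-skewed lesion count per patient (1-30), mostly two sections per
    lesion, ~5000 genes, and negative-binomial counts with moderate
    overdispersion and strong patient effects.
    """

    n_patients: int = 145
    lesions_range: tuple[int, int] = (1, 30)
    lesions_mean: float = 10.5  # mean of the truncated geometric lesion count
    sections_probs: tuple[float, float, float] = (0.22, 0.74, 0.04)  # P(1), P(2), P(3)
    n_genes: int = 5000
    program_sizes: dict = field(
        default_factory=lambda: {
            "basal": 400,
            "emt": 300,
            "proliferation": 300,
            "marker": len(MARKER_GENES),
        }
    )
    basal_amplitude: float = 2.5  # log2 decline over the full continuum
    emt_amplitude: float = 2.0
    emt_peaks: tuple[float, float] = (0.25, 0.90)
    emt_widths: tuple[float, float] = (0.07, 0.05)
    prolif_amplitude: float = 0.5
    prolif_onset: float = 0.28  # switches on just after the first EMT peak
    prolif_scale: float = 0.02
    marker_effect: float = 3.0  # log2 shift of the low marker state
    marker_low_prob_notpure: float = 0.70
    marker_low_prob_pure: float = 0.25
    frac_pure_dcis: float = 0.30  # P(patient is Pure DCIS, i.e. never gets IDC)
    frac_idc_biopsy_notpure: float = 0.50  # P(IDC lesions in biopsy | Not Pure)
    nb_dispersion: float = 0.10
    patient_sd: float = 0.70  # per-patient per-gene log2 random effect
    libsize_range: tuple[float, float] = (6e5, 2.5e6)
    frac_low_quality: float = 0.0
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("empty cohort")
        if sum(self.program_sizes.values()) + len(RECEPTOR_GENES) > self.n_genes:
            raise ValueError("program sizes exceed n_genes")
        for frac in (self.frac_pure_dcis, self.frac_low_quality):
            if not 0 <= frac <= 1:
                raise ValueError("proportions must be in [0, 1]")
        if not (1 <= self.lesions_range[0] <= self.lesions_range[1]):
            raise ValueError("invalid lesion range")
        if self.nb_dispersion < 0 or self.patient_sd < 0:
            raise ValueError("dispersion and patient_sd must be nonnegative")
        if not 0 < self.libsize_range[0] <= self.libsize_range[1]:
            raise ValueError("invalid library size range")
        return self


@dataclass
class Truth:
    """Ground truth for recovery tests."""

    t: pd.Series  # latent progression per sample
    program_membership: pd.Series  # gene -> program label
    marker_effect: pd.Series  # marker gene -> planted log2 shift
    marker_low_state: pd.DataFrame  # patients x marker genes, low-state indicator
    injected_bad: pd.Series  # sample -> low-quality flag


def _emt_profile(t: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    (p1, p2), (w1, w2) = cfg.emt_peaks, cfg.emt_widths
    return np.exp(-0.5 * ((t - p1) / w1) ** 2) + np.exp(-0.5 * ((t - p2) / w2) ** 2)


def _prolif_profile(t: np.ndarray, cfg: CohortConfig) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - cfg.prolif_onset) / cfg.prolif_scale))


def program_mean_shift(t: np.ndarray, program: str, cfg: CohortConfig) -> np.ndarray:
    """Planted log2 mean shift of a program as a function of latent ``t``."""
    if program == "basal":
        return cfg.basal_amplitude * (1.0 - t)
    if program == "emt":
        return cfg.emt_amplitude * _emt_profile(t, cfg)
    if program == "proliferation":
        return cfg.prolif_amplitude * _prolif_profile(t, cfg)
    return np.zeros_like(t)


def _sample_lesion_counts(rng: np.random.Generator, cfg: CohortConfig) -> np.ndarray:
    """Right-skewed lesion counts per patient, truncated to the configured range."""
    lo, hi = cfg.lesions_range
    p = 1.0 / max(cfg.lesions_mean - lo + 1, 1.0)
    counts = lo + rng.geometric(p, cfg.n_patients) - 1
    return np.clip(counts, lo, hi)


def simulate_cohort(config: CohortConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame, Truth]:
    """Generate (counts, sample metadata, truth) for one synthetic cohort.

    Same seed gives byte-identical outputs. When ``config.frac_low_quality``
    is positive the corresponding fraction of samples is corrupted via
    :func:`inject_low_quality` after generation.
    """
    cfg = (config or CohortConfig()).validate()
    rng = np.random.default_rng(cfg.seed)

    # ---- cohort layout ------------------------------------------------------
    # Patient outcome first: Pure DCIS patients never carry IDC lesions, and
    # only a fraction of Not-Pure patients have IDC in the dissected biopsy
    # (the rest were diagnosed elsewhere / later). Within the DCIS tissue
    # band the latent t distribution is identical for Pure and Not-Pure, so
    # position on the continuum does not encode the outcome.
    lesion_counts = _sample_lesion_counts(rng, cfg)
    pure_flags = rng.random(cfg.n_patients) < cfg.frac_pure_dcis
    idc_biopsy = (~pure_flags) & (rng.random(cfg.n_patients) < cfg.frac_idc_biopsy_notpure)
    tissues_order = list(TISSUES)
    mix_no = np.array([TISSUE_MIX_NO_IDC[t] for t in tissues_order])
    mix_no = mix_no / mix_no.sum()
    mix_idc = np.array([TISSUE_MIX_WITH_IDC[t] for t in tissues_order])
    mix_idc = mix_idc / mix_idc.sum()

    rows = []
    for p_idx in range(cfg.n_patients):
        pid = f"P{p_idx + 1:03d}"
        mix = mix_idc if idc_biopsy[p_idx] else mix_no
        for l_idx in range(lesion_counts[p_idx]):
            lid = f"{pid}.L{l_idx + 1:02d}"
            tissue = tissues_order[rng.choice(len(tissues_order), p=mix)]
            lo, hi = TISSUE_T_BANDS[tissue]
            t = rng.uniform(lo, hi)
            n_sections = 1 + rng.choice(3, p=np.array(cfg.sections_probs))
            for s_idx in range(n_sections):
                rows.append((pid, lid, s_idx + 1, tissue, t))
    meta = pd.DataFrame(rows, columns=["patient", "lesion", "section", "tissue", "_t"])
    meta.index = pd.Index(
        [f"{r.lesion}.S{r.section}" for r in meta.itertuples()], name="sample_id"
    )
    n_samples = len(meta)

    patients = meta["patient"].unique()
    pat_row = {f"P{p + 1:03d}": p for p in range(cfg.n_patients)}
    status = pd.Series(
        ["Pure" if pure_flags[pat_row[p]] else "NotPure" for p in patients], index=patients
    )
    meta["patient_status"] = meta["patient"].map(status).to_numpy()

    # molecular subtype and clinical receptor calls per patient
    subtype_levels = np.array(["LumA", "LumB", "Her2", "Basal", "Normal"])
    subtype_probs = np.array([0.45, 0.15, 0.15, 0.12, 0.13])
    subtype = pd.Series(
        subtype_levels[rng.choice(5, patients.size, p=subtype_probs)], index=patients
    )
    meta["subtype"] = meta["patient"].map(subtype).to_numpy()
    er_pos = (subtype != "Basal") & (rng.random(patients.size) < 0.9)
    pr_pos = er_pos & (rng.random(patients.size) < 0.8)
    her2_pos = (subtype == "Her2") | (rng.random(patients.size) < 0.1)
    for name, flags in (("er_status", er_pos), ("pr_status", pr_pos), ("her2_status", her2_pos)):
        calls = pd.Series(np.where(flags, "pos", "neg"), index=patients)
        meta[name] = meta["patient"].map(calls).to_numpy()

    # ---- gene annotation ----------------------------------------------------
    sizes = dict(cfg.program_sizes)
    sizes.setdefault("marker", len(MARKER_GENES))
    if sizes["marker"] != len(MARKER_GENES):
        raise ValueError("marker block size is fixed by the named marker genes")
    gene_ids: list[str] = []
    labels: list[str] = []
    counter = 0
    for prog in ("basal", "emt", "proliferation"):
        for _ in range(sizes.get(prog, 0)):
            counter += 1
            gene_ids.append(f"G{counter:05d}")
            labels.append(prog)
    gene_ids += list(MARKER_GENES)
    labels += ["marker"] * len(MARKER_GENES)
    gene_ids += list(RECEPTOR_GENES)
    labels += ["receptor"] * len(RECEPTOR_GENES)
    while len(gene_ids) < cfg.n_genes:
        counter += 1
        gene_ids.append(f"G{counter:05d}")
        labels.append("background")
    membership = pd.Series(labels, index=pd.Index(gene_ids, name="gene_id"))

    # ---- expression model ---------------------------------------------------
    t = meta["_t"].to_numpy()
    base = rng.normal(3.5, 1.5, cfg.n_genes).clip(min=0.0)
    logmu = np.tile(base[:, None], (1, n_samples))
    lab = membership.to_numpy()
    for prog in ("basal", "emt", "proliferation"):
        sel = lab == prog
        if sel.any():
            logmu[sel] += program_mean_shift(t, prog, cfg)[None, :]

    # marker genes: patient-level bimodal states linked to outcome
    marker_low = {}
    marker_effects = {}
    pat_index = pd.Index(patients, name="patient")
    pat_pos = {p: i for i, p in enumerate(patients)}
    sample_pat = np.array([pat_pos[p] for p in meta["patient"]])
    for g in MARKER_GENES:
        p_low = np.where(
            status.loc[patients] == "NotPure",
            cfg.marker_low_prob_notpure,
            cfg.marker_low_prob_pure,
        )
        if MARKER_DIRECTIONS[g] == "high":
            # IDC-associated state is HIGH: Not-Pure patients sit high more often
            p_low = 1.0 - p_low
        low = rng.random(patients.size) < p_low
        marker_low[g] = low
        marker_effects[g] = cfg.marker_effect
        gi = gene_ids.index(g)
        logmu[gi] = base[gi] + cfg.marker_effect / 2.0  # high state
        logmu[gi, low[sample_pat]] -= cfg.marker_effect
    marker_low_df = pd.DataFrame(marker_low, index=pat_index)

    # receptor transcripts: bimodal by clinical receptor status around the
    # conventional log2-CPM calling thresholds (6 / 6 / 10.5)
    rec_targets = {"ESR1": ("er_status", 8.0, 3.5), "PGR": ("pr_status", 8.0, 3.5), "ERBB2": ("ERBB2", 12.0, 9.0)}
    for g in RECEPTOR_GENES:
        gi = gene_ids.index(g)
        if g == "ERBB2":
            pos = meta["her2_status"].to_numpy() == "pos"
            hi, lo_ = rec_targets[g][1], rec_targets[g][2]
        else:
            col, hi, lo_ = rec_targets[g]
            pos = meta[col].to_numpy() == "pos"
        logmu[gi] = np.where(pos, hi, lo_)

    # per-patient per-gene random effect (inter-patient heterogeneity)
    pat_eff = rng.normal(0.0, cfg.patient_sd, (cfg.n_genes, patients.size))
    logmu += pat_eff[:, sample_pat]

    # ---- negative-binomial sampling ----------------------------------------
    lib = rng.uniform(cfg.libsize_range[0], cfg.libsize_range[1], n_samples)
    w = np.exp2(logmu)
    frac = w / w.sum(axis=0, keepdims=True)
    mean = frac * lib[None, :]
    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=membership.index, columns=meta.index)

    truth = Truth(
        t=meta["_t"].rename("t"),
        program_membership=membership,
        marker_effect=pd.Series(marker_effects, name="marker_effect"),
        marker_low_state=marker_low_df,
        injected_bad=pd.Series(False, index=meta.index, name="injected_bad"),
    )
    meta = meta.drop(columns="_t")

    if cfg.frac_low_quality > 0:
        counts_df, flags = inject_low_quality(
            counts_df, meta, cfg.frac_low_quality, seed=cfg.seed + 1
        )
        truth.injected_bad = flags
    return counts_df, meta, truth


def inject_low_quality(
    counts: pd.DataFrame, meta: pd.DataFrame, frac: float, seed: int
) -> tuple[pd.DataFrame, pd.Series]:
    """Corrupt a fraction of samples so the correlation QC must catch them.

    Selected samples get their counts shuffled across genes (destroying the
    shared expression profile) and their depth cut 10-fold. Returns the new
    matrix and a per-sample flag series.
    """
    if not 0 <= frac < 0.5:
        raise ValueError("frac must be in [0, 0.5)")
    flags = pd.Series(False, index=counts.columns, name="injected_bad")
    if frac == 0:
        return counts, flags
    rng = np.random.default_rng(seed)
    n_bad = int(round(frac * counts.shape[1]))
    bad = rng.choice(counts.shape[1], size=n_bad, replace=False)
    out = counts.to_numpy().copy()
    for j in bad:
        perm = rng.permutation(out.shape[0])
        col = out[perm, j] / 10.0
        out[:, j] = rng.poisson(col)
    flags.iloc[bad] = True
    return pd.DataFrame(out, index=counts.index, columns=counts.columns), flags


def simulate_libstats(
    meta: pd.DataFrame, seed: int, frac_fail: float = 0.0
) -> pd.DataFrame:
    """Per-sample raw library metrics (reads, % unique mapping, % in genes).

    A ``frac_fail`` fraction of samples is given metrics below at least one
    of the conventional failure thresholds.
    """
    rng = np.random.default_rng(seed)
    n = len(meta)
    stats = pd.DataFrame(
        {
            "raw_reads": rng.uniform(2e6, 2e7, n),
            "pct_unique_map": rng.uniform(40.0, 90.0, n),
            "pct_reads_in_genes": rng.uniform(20.0, 70.0, n),
        },
        index=meta.index,
    )
    n_fail = int(round(frac_fail * n))
    if n_fail:
        fail_idx = rng.choice(n, size=n_fail, replace=False)
        which = rng.choice(3, size=n_fail)
        cols = ["raw_reads", "pct_unique_map", "pct_reads_in_genes"]
        bad_vals = [rng.uniform(1e5, 9e5, n_fail), rng.uniform(1.0, 14.0, n_fail), rng.uniform(0.5, 4.0, n_fail)]
        for k in range(n_fail):
            stats.iloc[fail_idx[k], stats.columns.get_loc(cols[which[k]])] = bad_vals[which[k]][k]
    return stats


def default_config(**overrides) -> CohortConfig:
    """The study-condition defaults, optionally overridden field-by-field."""
    return replace(CohortConfig(), **overrides).validate()
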