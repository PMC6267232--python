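"""End-to-end orchestration: cohort -> connectivity/MST features -> tables.

Produces the three result tables of the analysis:

``cognition_group``
    per cognitive domain, patient and control z-score mean/SD and a
    Mann-Whitney U test (one-tailed by default: patients worse).
``rsn_mst_correlations``
    Kendall tau-b between a cognitive domain and, per band, the mean PLI
    in each of the three RSNs plus the five MST metrics (8 columns/band).
``global_correlations``
    Kendall tau-b between each of the six domains and the global mean PLI
    per band.

Brain-behaviour correlations run on the patient group (the emulated study
has no control MEG) and, by default, only for domains whose group
comparison is significant at p < 0.05; ``all_domains=True`` overrides the
gate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity, io, msttree, spectral, stats
from .cognition import DEFAULT_BATTERY, DOMAINS, profile_subject
from .errors import ValidationError
from .io import AtlasDefinition, RoiTimeSeries
from .msttree import METRIC_NAMES
from .spectral import DEFAULT_BANDS, BandDefinition
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("mnc")

RSN_ORDER = ("DMN", "FPN_left", "FPN_right")
ALPHA = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    atlas_path: str | None = None
    rsns: tuple[str, ...] = RSN_ORDER
    edge_trim: bool = True
    group_sidedness: str = "one"
    correlation_sidedness: str = "two"
    all_domains: bool = False
    bh_correction: bool = False
    output_dir: str = "mnc_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        bands = cohort_raw.pop("bands", None)
        if bands is not None:
            cohort_raw["bands"] = tuple(
                BandDefinition(b["name"], float(b["lo_hz"]), float(b["hi_hz"]))
                for b in bands
            )
        known = {f for f in cls.__dataclass_fields__} - {"cohort"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown run-config keys: {sorted(unknown)}")
        if "rsns" in raw:
            raw["rsns"] = tuple(raw["rsns"])
        return cls(cohort=CohortConfig(**cohort_raw), **raw)


# ---------------------------------------------------------------------------
# feature extraction


def subject_band_features(
    ts: RoiTimeSeries,
    band: BandDefinition,
    atlas: AtlasDefinition,
    epoch_samples: int,
    rsns: tuple[str, ...] = RSN_ORDER,
    edge_trim: bool = True,
) -> dict[str, float]:
    """PLI RSN/global means and epoch-averaged MST metrics for one band."""
    epochs = spectral.phase_epochs(ts, band, epoch_samples)
    mats = [
        connectivity.pli_matrix(ep, ts.roi_labels, edge_trim=edge_trim)
        for ep in epochs
    ]
    averaged = connectivity.average_epochs(mats)
    feats: dict[str, float] = {}
    for rsn in rsns:
        feats[f"pli_{rsn}"] = connectivity.rsn_mean(averaged, atlas, rsn)
    feats["pli_global"] = connectivity.global_mean(averaged)
    profile = msttree.subject_mst_profile(mats)
    for name in METRIC_NAMES:
        feats[f"mst_{name}"] = getattr(profile, name)
    return feats


def compute_features(
    cohort: SyntheticCohort,
    rsns: tuple[str, ...] = RSN_ORDER,
    edge_trim: bool = True,
) -> pd.DataFrame:
    """Tidy per-subject x band feature table for every subject with MEG."""
    rows = []
    for subject in cohort.subjects:
        for band_name, ts in subject.timeseries.items():
            band = cohort.config.band(band_name)
            logger.debug("features: subject=%s band=%s", subject.subject_id, band_name)
            feats = subject_band_features(
                ts, band, cohort.atlas, cohort.config.epoch_samples,
                rsns=rsns, edge_trim=edge_trim,
            )
            rows.append(
                {"subject_id": subject.subject_id, "group": subject.group,
                 "band": band_name, **feats}
            )
    return pd.DataFrame(rows)


def domain_zscores(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-subject cognitive domain z-scores against the control norms."""
    table = cohort.cognitive_table()
    rows = []
    for subject in cohort.subjects:
        prof = profile_subject(
            subject.subject_id, subject.raw_scores, table, cohort.battery
        )
        for domain in DOMAINS:
            rows.append(
                {"subject_id": subject.subject_id, "group": subject.group,
                 "domain": domain, "z": prof.domain_z[domain],
                 "impaired": prof.impaired[domain]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# result tables


def run_group_comparison(
    cohort: SyntheticCohort, sidedness: str = "one", zscores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Patient-vs-control comparison of the six domain z-scores."""
    z = zscores if zscores is not None else domain_zscores(cohort)
    if not len(cohort.patients) or not len(cohort.controls):
        raise ValidationError("both groups must be non-empty")
    rows = []
    for domain in DOMAINS:
        sub = z[z["domain"] == domain]
        if sub.empty:
            raise ValidationError(f"missing domain {domain!r}")
        pat = sub[sub["group"] == "patient"]["z"].to_numpy()
        con = sub[sub["group"] == "control"]["z"].to_numpy()
        # one-tailed alternative: patients score lower than controls
        res = stats.mann_whitney_u(pat, con, sidedness=sidedness, direction="less")
        rows.append(
            {
                "domain": domain,
                "patient_mean": pat.mean(), "patient_sd": pat.std(ddof=1),
                "control_mean": con.mean(), "control_sd": con.std(ddof=1),
                "mann_whitney_u": res.statistic, "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def _correlate(
    merged: pd.DataFrame, measures: list[str], sidedness: str
) -> list[dict]:
    rows = []
    for band_name, sub in merged.groupby("band", sort=False):
        for measure in measures:
            res = stats.kendall_tau_b(
                sub["z"].to_numpy(), sub[measure].to_numpy(), sidedness=sidedness
            )
            rows.append(
                {"band": band_name, "measure": measure,
                 "tau": res.statistic, "p_value": res.p_value, "n": res.n1}
            )
    return rows


def run_brain_behaviour(
    cohort: SyntheticCohort,
    domain: str,
    features: pd.DataFrame | None = None,
    zscores: pd.DataFrame | None = None,
    rsns: tuple[str, ...] = RSN_ORDER,
    sidedness: str = "two",
) -> pd.DataFrame:
    """Kendall tau-b of one domain vs RSN PLI and MST metrics, per band."""
    if domain not in DOMAINS:
        raise ValidationError(f"unknown domain {domain!r}")
    feats = features if features is not None else compute_features(cohort, rsns=rsns)
    feats = feats[feats["group"] == "patient"]
    z = zscores if zscores is not None else domain_zscores(cohort)
    z = z[(z["domain"] == domain) & (z["group"] == "patient")][["subject_id", "z"]]
    merged = feats.merge(z, on="subject_id")
    if merged["subject_id"].nunique() < 3:
        raise ValidationError("need at least 3 subjects with MEG and cognition")
    measures = [f"pli_{rsn}" for rsn in rsns] + [f"mst_{m}" for m in METRIC_NAMES]
    rows = _correlate(merged, measures, sidedness)
    out = pd.DataFrame(rows)
    out.insert(0, "domain", domain)
    return out


def run_global_correlations(
    cohort: SyntheticCohort,
    features: pd.DataFrame | None = None,
    zscores: pd.DataFrame | None = None,
    sidedness: str = "two",
) -> pd.DataFrame:
    """Kendall tau-b of each domain vs global mean PLI, per band."""
    feats = features if features is not None else compute_features(cohort)
    feats = feats[feats["group"] == "patient"]
    z_all = zscores if zscores is not None else domain_zscores(cohort)
    rows = []
    for domain in DOMAINS:
        z = z_all[(z_all["domain"] == domain) & (z_all["group"] == "patient")][
            ["subject_id", "z"]
        ]
        merged = feats.merge(z, on="subject_id")
        if merged["subject_id"].nunique() < 3:
            raise ValidationError("need at least 3 subjects with MEG and cognition")
        for row in _correlate(merged, ["pli_global"], sidedness):
            rows.append({"domain": domain, **row})
    return pd.DataFrame(rows)


def dmn_working_memory_association(
    cohort: SyntheticCohort, sidedness: str = "two"
) -> dict[str, float]:
    """The headline analysis: effect-RSN PLI vs working memory, plus the
    patient-vs-control working-memory group test.

    PLI is computed on the effect-RSN sub-matrix only — pairwise PLI does
    not depend on other ROIs — which keeps repeated-cohort simulations
    cheap.  Returns the Kendall tau-b and p for patients' epoch-averaged
    within-RSN PLI against their working-memory z-score, and the one-tailed
    (patients worse) Mann-Whitney U and p for working memory.
    """
    config = cohort.config
    band = config.band(config.effect_band)
    idx = cohort.atlas.rsn_indices(config.effect_rsn)
    iu = np.triu_indices(idx.size, k=1)
    z = domain_zscores(cohort)
    wm = z[z["domain"] == "working_memory"]
    wm_pat = wm[wm["group"] == "patient"].set_index("subject_id")["z"]
    wm_con = wm[wm["group"] == "control"]["z"].to_numpy()

    plis, zs = [], []
    for subject in cohort.patients:
        ts = subject.timeseries[config.effect_band]
        epochs = spectral.phase_epochs(ts, band, config.epoch_samples)
        vals = [
            connectivity.pli_matrix(
                spectral.PhaseEpoch(ep.phases[idx], ep.band, ep.epoch_index)
            ).values[iu].mean()
            for ep in epochs
        ]
        plis.append(float(np.mean(vals)))
        zs.append(float(wm_pat[subject.subject_id]))
    tau = stats.kendall_tau_b(plis, zs, sidedness=sidedness)
    out = {"tau": tau.statistic, "tau_p": tau.p_value, "n_patients": tau.n1}
    if wm_con.size:
        u = stats.mann_whitney_u(
            np.array(zs), wm_con, sidedness="one", direction="less"
        )
        out.update({"wm_u": u.statistic, "wm_p": u.p_value})
    return out


# ---------------------------------------------------------------------------
# full run


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {
            "cohort": {
                k: (list(map(str, v)) if isinstance(v, tuple) else v)
                for k, v in config.cohort.__dict__.items()
            },
            **{k: v for k, v in config.__dict__.items() if k != "cohort"},
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig, output_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Execute the full pipeline and write tables plus a JSON manifest."""
    from importlib.metadata import version

    atlas = io.read_atlas(config.atlas_path) if config.atlas_path else None
    logger.info("generating cohort (seed=%d)", config.cohort.seed)
    cohort = generate_cohort(config.cohort, atlas=atlas)
    zscores = domain_zscores(cohort)
    group_table = run_group_comparison(cohort, config.group_sidedness, zscores)

    logger.info("computing connectivity and MST features")
    features = compute_features(cohort, rsns=config.rsns, edge_trim=config.edge_trim)

    if config.all_domains:
        selected = list(DOMAINS)
    else:
        selected = group_table[group_table["p_value"] < ALPHA]["domain"].tolist()
        logger.info("domains passing the group gate (p < %.2f): %s", ALPHA, selected)
    rsn_tables = [
        run_brain_behaviour(
            cohort, domain, features, zscores, config.rsns,
            config.correlation_sidedness,
        )
        for domain in selected
    ]
    rsn_mst = (
        pd.concat(rsn_tables, ignore_index=True)
        if rsn_tables
        else pd.DataFrame(columns=["domain", "band", "measure", "tau", "p_value", "n"])
    )
    global_table = run_global_correlations(
        cohort, features, zscores, config.correlation_sidedness
    )
    if config.bh_correction:
        for tbl in (rsn_mst, global_table):
            if len(tbl):
                tbl["p_bh"] = stats.benjamini_hochberg(tbl["p_value"].to_numpy())

    tables = {
        "cognition_group": group_table,
        "rsn_mst_correlations": rsn_mst,
        "global_correlations": global_table,
    }
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.cohort.seed,
        "n_patients": config.cohort.n_patients,
        "n_controls": config.cohort.n_controls,
        "bands": [b.name for b in config.cohort.bands],
        "package_version": version("mnc"),
    }
    io.write_report(tables, outdir, manifest)
    logger.info("wrote %d tables to %s", len(tables), outdir)
    return tables
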