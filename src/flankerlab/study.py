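"""End-to-end study orchestration.

``run_study`` chains every stage for a (synthetic or loaded) cohort:
behavioral scoring and congruency x group ANOVA; EEG preprocessing to
per-subject ERPs with the inclusion gate; the sliding 20-ms window
analysis, cluster discovery and window ANOVAs (mean amplitude and peak
measures); fNIRS hemoglobin conversion, GLM and chromophore ANOVAs.
Every excluded subject or epoch is logged with the rule that removed
it, and all output tables carry the config hash and seed.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import behavior, eeg, erp, fnirs
from .paradigm import MAINLY_CONGRUENT, MAINLY_INCONGRUENT
from .stats import StatResult
from .synthetic import EffectConfig, NoiseConfig, SubjectDataset, iter_cohort

__all__ = ["StudyConfig", "SubjectResult", "StudyResult", "process_subject",
           "run_study"]

_CONDS = ("congruent", "incongruent")
_BLOCK_TYPES = (MAINLY_CONGRUENT, MAINLY_INCONGRUENT)


@dataclass
class StudyConfig:
    """All knobs of one study run; schema-validated on load."""

    n_patients: int = 28
    n_controls: int = 29
    seed: int = 0
    lowpass_hz: float = 50.0
    notch_hz: float = 50.0
    rejection: eeg.RejectionCriteria = field(default_factory=eeg.RejectionCriteria)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    total_per_condition: int = 120
    min_electrodes: int = 15
    discover_windows: bool = True
    analysis_windows: tuple = erp.DEFAULT_WINDOWS
    negative_peak_window: tuple[float, float] = (260.0, 300.0)
    positive_peak_window: tuple[float, float] = (300.0, 660.0)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("rejection", eeg.RejectionCriteria),
                         ("effects", EffectConfig), ("noise", NoiseConfig)):
            if key in raw and isinstance(raw[key], dict):
                bad = set(raw[key]) - set(sub.__dataclass_fields__)
                if bad:
                    raise ValueError(f"unknown {key} keys: {sorted(bad)}")
                raw[key] = sub(**raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _plain(x):
    if isinstance(x, dict):
        return {str(k): _plain(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plain(v) for v in x]
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    return x


@dataclass
class SubjectResult:
    subject: str
    group: str
    summary: behavior.BehavioralSummary
    included: bool
    gate: dict
    erps: eeg.ErpSet | None
    ocular_coeffs: dict
    fnirs_betas: dict  # chromophore -> (2, n_channels) [congruent-type first]
    log: list[str]


def process_subject(dataset: SubjectDataset, config: StudyConfig) -> SubjectResult:
    """Run the full per-subject chain: behavior, EEG-to-ERP, fNIRS GLM."""
    log: list[str] = []
    scored = behavior.score_log(dataset.schedule, dataset.responses)
    summary = behavior.summarize_subject(scored, dataset.subject, dataset.group)

    correct_ids = [s.trial.index for s in scored if s.outcome == behavior.CORRECT]
    filtered = eeg.filter_continuous(dataset.eeg, config.lowpass_hz, config.notch_hz)
    epochs, dropped = eeg.segment(filtered, correct_ids)
    for idx in dropped:
        log.append(f"epoch dropped (recording edge): trial {idx}")
    epochs, coeffs = eeg.ocular_correct(epochs)
    epochs, report = eeg.reject_artifacts(epochs, config.rejection)
    log.append(f"artifact rejection: {report['n_rejected_cells']} epoch x channel cells")
    included, gate = eeg.gate_subject(epochs, config.total_per_condition,
                                      config.min_electrodes)
    erps = None
    if included:
        epochs = eeg.baseline_and_rereference(epochs)
        erps = eeg.average_erp(epochs)
    else:
        log.append(f"subject excluded: cut-off of {gate['cutoff']} trials "
                   f"not reached on {config.min_electrodes} electrodes")

    hemo = fnirs.mbll_convert(dataset.fnirs)
    hbo = fnirs.lowpass_04(fnirs.interpolate_artifacts_rows(hemo.hbo), hemo.sfreq)
    hbr = fnirs.lowpass_04(fnirs.interpolate_artifacts_rows(hemo.hbr), hemo.sfreq)
    design = fnirs.build_design(dataset.schedule, hemo.sfreq, hbo.shape[1])
    fit = fnirs.glm_fit(replace(hemo, hbo=hbo, hbr=hbr), design)
    betas = {}
    for chrom in ("hbo", "hbr"):
        tab = fit.condition_betas(chrom)
        betas[chrom] = np.stack([tab[bt].to_numpy() for bt in _BLOCK_TYPES])

    return SubjectResult(dataset.subject, dataset.group, summary, included,
                         gate, erps, coeffs, betas, log)


@dataclass
class StudyResult:
    config: StudyConfig
    subjects: list[SubjectResult]
    behavioral: dict
    window_tests: pd.DataFrame
    clusters: list[erp.WindowCluster]
    analysis_windows: list[tuple[float, float]]
    erp_anovas: dict
    fnirs_anovas: dict
    log: list[str]

    @property
    def n_included(self) -> int:
        return sum(s.included for s in self.subjects)

    def provenance(self) -> dict:
        return {"config_hash": self.config.digest(), "seed": self.config.seed}

    def write_tables(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        prov = self.provenance()

        def _save(df: pd.DataFrame, name: str) -> None:
            df = df.copy()
            for key, val in prov.items():
                df[key] = val
            df.to_csv(os.path.join(out_dir, name), sep="\t", index=False)

        rows = [{"subject": s.subject, "group": s.group, "included": s.included,
                 **{f"rt_{c}": s.summary.mean_rt[c] for c in _CONDS},
                 **{f"acc_{c}": s.summary.accuracy[c] for c in _CONDS}}
                for s in self.subjects]
        _save(pd.DataFrame(rows), "behavior_subjects.tsv")
        _save(_stats_frame({k: v for k, v in self.behavioral.items()
                            if k != "dropped_rt"}), "behavior_anova.tsv")
        _save(self.window_tests, "window_ttests.tsv")
        _save(pd.DataFrame([{"start_ms": c.start_ms, "end_ms": c.end_ms,
                             "group": c.group, "sign": c.sign,
                             "electrodes": ",".join(c.electrodes)}
                            for c in self.clusters]), "window_clusters.tsv")
        _save(_stats_frame({k: v["anova"] for k, v in self.erp_anovas.items()}),
              "erp_anovas.tsv")
        for key, block in self.erp_anovas.items():
            if block.get("posthoc") is not None:
                _save(block["posthoc"], f"posthoc_{key}.tsv")
        _save(_stats_frame({k: v["anova"] for k, v in self.fnirs_anovas.items()}),
              "fnirs_anovas.tsv")
        with open(os.path.join(out_dir, "processing_log.txt"), "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump(_plain(asdict(self.config)), fh, sort_keys=True)


def _stats_frame(named_results: dict[str, list[StatResult]]) -> pd.DataFrame:
    rows = []
    for name, results in named_results.items():
        for r in results:
            rows.append({"analysis": name, "effect": r.effect, "kind": r.kind,
                         "statistic": r.statistic, "df1": r.df[0], "df2": r.df[1],
                         "epsilon": r.epsilon, "p_raw": r.p_raw, "p": r.p,
                         "gg_applied": r.correction_applied})
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, datasets=None) -> StudyResult:
    """Run the whole analysis; deterministic given config (and datasets).

    ``datasets`` may be any iterable of :class:`SubjectDataset`; when
    None a synthetic cohort is generated from the config.  Subjects are
    processed one at a time so continuous recordings never accumulate in
    memory.
    """
    if datasets is None:
        datasets = (ds for ds, _truth in iter_cohort(
            config.n_patients, config.n_controls, config.effects, config.noise,
            config.seed))
    log: list[str] = []
    subjects: list[SubjectResult] = []
    for ds in datasets:
        res = process_subject(ds, config)
        subjects.append(res)
        log.extend(f"{res.subject}: {line}" for line in res.log)

    behavioral = behavior.behavioral_anova([s.summary for s in subjects])
    for sub in behavioral["dropped_rt"]:
        log.append(f"{sub}: dropped from RT ANOVA (empty condition cell)")

    included = [s for s in subjects if s.included]
    group_counts = pd.Series([s.group for s in included]).value_counts()
    if len(group_counts) == 0 or group_counts.min() < 2:
        raise RuntimeError("fewer than 2 included subjects per group after gating")
    erps = [s.erps for s in included]
    groups = [s.group for s in included]

    window_tests = erp.sliding_window_ttests(erps, groups)
    clusters = erp.find_clusters(window_tests)
    if config.discover_windows and clusters:
        windows = erp.union_windows(clusters)
    else:
        windows = [tuple(w) for w in config.analysis_windows]

    erp_anovas: dict[str, dict] = {}
    for win in windows:
        vals = erp.measures_table(erps, win, kind="mean")
        res, posthoc, dropped = erp.erp_anova(vals, groups)
        erp_anovas[f"mean_{win[0]:.0f}_{win[1]:.0f}"] = {
            "anova": res, "posthoc": posthoc, "window": win}
        for d in dropped:
            log.append(f"{included[d].subject}: dropped from {win} mean ANOVA")
    for name, win, polarity in (
            ("negative_peak", config.negative_peak_window, "negative"),
            ("positive_peak", config.positive_peak_window, "positive")):
        for value in ("amplitude", "latency"):
            vals = erp.measures_table(erps, win, kind="peak", polarity=polarity,
                                      value=value)
            res, posthoc, _ = erp.erp_anova(vals, groups)
            erp_anovas[f"{name}_{value}"] = {"anova": res, "posthoc": posthoc,
                                             "window": win}

    fnirs_anovas: dict[str, dict] = {}
    for chrom in ("hbo", "hbr"):
        betas = np.stack([s.fnirs_betas[chrom] for s in subjects])  # (subj, 2, ch)
        res, dropped = fnirs.fnirs_anova(betas, [s.group for s in subjects])
        fnirs_anovas[chrom] = {"anova": res}
        for d in dropped:
            log.append(f"{subjects[d].subject}: dropped from fNIRS {chrom} ANOVA")

    return StudyResult(config, subjects, behavioral, window_tests, clusters,
                       windows, erp_anovas, fnirs_anovas, log)
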