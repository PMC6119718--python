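"""Run every stimulus x dimension x factor test and correct for multiplicity.

The battery enumerates the full cross product of stimuli, affect dimensions
and grouping factors (e.g. 17 stimuli x 2 dimensions x 9 factors = 306
tests), skips cells excluded by the reliability screen (while still counting
them in the enumeration), runs the bootstrap functional ANOVA on the rest
with deterministically derived per-test seeds, and applies the
Benjamini-Hochberg step-up correction within configurable families.  A
Bonferroni adjustment is available as the conservative baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import (
    BATTERY_COLUMNS,
    BatteryResult,
    StimulusInfo,
    StudyDataset,
    ValidationError,
    write_battery_results,
)
from .fanova import BootstrapSpec, ConfigError, FunctionalANOVA, SmoothingSpec, select_bandwidth
from .preprocess import (
    DEFAULT_RELIABILITY_THRESHOLD,
    apply_reliability_filter,
    reliability_table,
)

logger = logging.getLogger("affectfanova")

FAMILY_MODES = ("per_stimulus", "global")


class BatteryError(RuntimeError):
    """Too many individual tests failed for the battery to be trusted."""


def enumerate_tests(stimuli, dimensions, factors, excluded_pairs=()) -> pd.DataFrame:
    """The ordered cross product of stimuli x dimensions x factors.

    ``stimuli`` may be StimulusInfo objects or (stimulus_id, modality)
    pairs.  Ordering is (modality, stimulus, dimension, factor) with the
    given within-modality stimulus order preserved.  Reliability-excluded
    stimulus x dimension pairs stay in the enumeration (they count toward
    the battery size) but are flagged for skipping.
    """
    if not stimuli or not dimensions or not factors:
        raise ValidationError("stimuli, dimensions and factors must be non-empty")
    norm = []
    for s in stimuli:
        if isinstance(s, StimulusInfo):
            norm.append((s.stimulus_id, s.modality))
        else:
            norm.append((str(s[0]), str(s[1])))
    factor_names = [f if isinstance(f, str) else f.name for f in factors]
    excluded = {(str(s), str(d)) for s, d in excluded_pairs}
    rows = []
    for modality in sorted({m for _, m in norm}):
        for sid, m in norm:
            if m != modality:
                continue
            for dim in dimensions:
                for fname in factor_names:
                    rows.append(
                        {
                            "modality": modality,
                            "stimulus_id": sid,
                            "dimension": dim,
                            "factor": fname,
                            "excluded_for_reliability": (sid, dim) in excluded,
                        }
                    )
    df = pd.DataFrame(rows)
    df.insert(0, "test_index", np.arange(len(df)))
    return df


def _validate_pvalues(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValidationError("p-values must lie in (0, 1]")
    return p


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR correction.

    Returns ``(p_adjusted, reject)``.  Adjusted values follow the usual
    step-up definition (monotone in the raw p-values); the rejection set
    equals the largest-k rule: reject the k smallest p-values where k is the
    largest index with p_(k) <= k q / m.
    """
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    p = _validate_pvalues(p_values)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni adjustment min(1, m p) — the conservative FWER baseline."""
    p = _validate_pvalues(p_values)
    return np.minimum(1.0, p * p.size)


def child_seed(master_seed, test_index: int) -> np.random.SeedSequence:
    """Deterministic, order-independent per-test seed derivation."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(int(test_index),))


@dataclass
class BatteryResults:
    """Fitted battery: result table plus reporting helpers."""

    result: BatteryResult

    @property
    def table(self) -> pd.DataFrame:
        return self.result.table

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def fraction_significant(self) -> float:
        ran = self.table["p_raw"].notna()
        return float(self.table["significant"].sum() / max(int(ran.sum()), 1))

    def top_hit(self):
        """(stimulus_id, dimension, factor) of the smallest adjusted p-value."""
        ran = self.table[self.table["p_adjusted"].notna()]
        if ran.empty:
            return None
        row = ran.sort_values(["p_adjusted", "p_raw", "test_index"]).iloc[0]
        return row["stimulus_id"], row["dimension"], row["factor"]

    def summary(self) -> str:
        tab = self.table
        ran = int(tab["p_raw"].notna().sum())
        lines = [
            "Functional ANOVA battery",
            "=" * 40,
            f"tests enumerated:   {len(tab)}",
            f"tests executed:     {ran}",
            f"reliability-excluded: {int(tab['excluded_for_reliability'].sum())}",
            f"failed:             {int(tab['error'].notna().sum())}",
            f"significant (BH):   {self.n_significant}"
            f" ({100 * self.n_significant / max(ran, 1):.1f}% of executed)",
        ]
        return "\n".join(lines)

    def significance_matrix(self) -> pd.DataFrame:
        """Factor x (modality, stimulus, dimension) grid of cell states."""
        tab = self.table.copy()

        def state(row):
            if row["excluded_for_reliability"]:
                return ""  # excluded cells render blank, not "ns"
            if isinstance(row["error"], str) and row["error"]:
                return "failed"
            return "sig" if row["significant"] else "ns"

        tab["state"] = tab.apply(state, axis=1)
        return tab.pivot_table(
            index="factor",
            columns=["modality", "stimulus_id", "dimension"],
            values="state",
            aggfunc="first",
            sort=False,
        )

    def save(self, path):
        write_battery_results(self.result, path)

    def plot_significance(self, fig_path=None, tsv_path=None, ax=None):
        """Render the significance grid; optionally write figure + TSV twin."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        grid = self.significance_matrix()
        if tsv_path is not None:
            grid.to_csv(tsv_path, sep="\t")
        if ax is None:
            fig, ax = plt.subplots(
                figsize=(max(6, 0.35 * grid.shape[1]), 0.5 * grid.shape[0] + 1.5)
            )
        else:
            fig = ax.figure
        for yi, factor in enumerate(grid.index):
            for xi, col in enumerate(grid.columns):
                val = grid.loc[factor, col]
                if val == "sig":
                    ax.scatter([xi], [yi], s=80, c="gray", edgecolors="black")
                elif val == "failed":
                    ax.scatter([xi], [yi], marker="x", s=40, c="red")
        ax.set_xticks(range(grid.shape[1]))
        ax.set_xticklabels(
            ["/".join(map(str, c)) for c in grid.columns], rotation=90, fontsize=7
        )
        ax.set_yticks(range(grid.shape[0]))
        ax.set_yticklabels(grid.index)
        ax.set_xlim(-0.5, grid.shape[1] - 0.5)
        ax.set_ylim(grid.shape[0] - 0.5, -0.5)
        ax.set_title("Significant group differences (BH-corrected)")
        fig.tight_layout()
        if fig_path is not None:
            fig.savefig(fig_path, dpi=150)
            plt.close(fig)
        return ax


class EmotionRatingBattery:
    """Model object running the full test battery over a study.

    Parameters
    ----------
    dataset : StudyDataset
        Preprocessed ratings (normalized, uniform grids).
    factors : mapping or sequence of GroupingFactor
    reliability : DataFrame, optional
        Output of :func:`affectfanova.preprocess.reliability_table`;
        computed from the dataset when omitted.
    smoothing : SmoothingSpec, optional
    family : {"per_stimulus", "global"}
        BH correction family: all tests of one stimulus, or the whole
        battery.
    """

    def __init__(
        self,
        dataset: StudyDataset,
        factors,
        reliability: pd.DataFrame | None = None,
        reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
        smoothing: SmoothingSpec | None = None,
        family: str = "per_stimulus",
        dimensions=("valence", "arousal"),
    ):
        if family not in FAMILY_MODES:
            raise ConfigError(f"family must be one of {FAMILY_MODES}")
        self.dataset = dataset
        self.factors = dict(factors) if not isinstance(factors, dict) else dict(factors)
        self.smoothing = smoothing or SmoothingSpec()
        self.family = family
        self.dimensions = tuple(dimensions)
        self.reliability_threshold = reliability_threshold
        if reliability is None:
            reliability = reliability_table(dataset, threshold=reliability_threshold)
        self.reliability = reliability

    def _stimuli(self):
        infos = list(self.dataset.stimuli.values())
        if infos:
            return infos
        # no metadata: fall back to ids found in the ratings, inferring the
        # modality from the identifier prefix (anything starting with "s"
        # counts as speech)
        out = []
        for sid in self.dataset.stimulus_ids:
            modality = "speech" if str(sid).lower().startswith("s") else "music"
            series = self.dataset.series(sid, self.dimensions[0])
            duration = len(series[0].t) if series else 1
            out.append(StimulusInfo(sid, modality, duration))
        return out

    def fit(
        self,
        q: float = 0.05,
        n_boot: int = 1000,
        seed=0,
        bootstrap: BootstrapSpec | None = None,
        max_failure_fraction: float = 0.10,
    ) -> BatteryResults:
        """Run all non-excluded tests and apply the BH correction.

        Child seeds derive from ``seed`` and each test's ordinal index in
        the canonical enumeration, so results do not depend on execution
        order and the same master seed reproduces the battery bit for bit.
        """
        _, excluded = apply_reliability_filter(self.reliability, self.reliability_threshold)
        tests = enumerate_tests(
            self._stimuli(), self.dimensions, list(self.factors), excluded_pairs=excluded
        )

        # one shared bandwidth per stimulus x dimension, for comparability
        bandwidths = {}
        for (sid, dim), flag in (
            tests.groupby(["stimulus_id", "dimension"])["excluded_for_reliability"]
            .first()
            .items()
        ):
            if flag or self.smoothing.bandwidth != "auto":
                continue
            t, mat, _ = self.dataset.curve_matrix(sid, dim)
            bandwidths[(sid, dim)] = select_bandwidth(
                mat, t, degree=self.smoothing.degree, kernel=self.smoothing.kernel
            )

        records = []
        n_failed = 0
        for row in tests.itertuples(index=False):
            rec = {
                "test_index": row.test_index,
                "modality": row.modality,
                "stimulus_id": row.stimulus_id,
                "dimension": row.dimension,
                "factor": row.factor,
                "n_a": np.nan,
                "n_b": np.nan,
                "statistic": np.nan,
                "bandwidth": np.nan,
                "p_raw": np.nan,
                "p_adjusted": np.nan,
                "significant": False,
                "excluded_for_reliability": bool(row.excluded_for_reliability),
                "error": None,
            }
            if not row.excluded_for_reliability:
                try:
                    model = FunctionalANOVA.from_dataset(
                        self.dataset,
                        row.stimulus_id,
                        row.dimension,
                        self.factors[row.factor],
                        smoothing=self.smoothing,
                    )
                    h = bandwidths.get((row.stimulus_id, row.dimension))
                    if h is None and self.smoothing.bandwidth != "auto":
                        h = self.smoothing.bandwidth
                    boot = BootstrapSpec(
                        n_boot=(bootstrap.n_boot if bootstrap else n_boot),
                        seed=child_seed(seed, row.test_index),
                    )
                    res = model.fit(bootstrap=boot, bandwidth=h)
                    rec.update(
                        n_a=res.n_a,
                        n_b=res.n_b,
                        statistic=res.statistic,
                        bandwidth=res.bandwidth,
                        p_raw=res.p_value,
                    )
                except Exception as exc:  # single-test failure: record, continue
                    n_failed += 1
                    rec["error"] = f"{type(exc).__name__}: {exc}"
                    logger.warning(
                        "test failed for %s/%s/%s: %s",
                        row.stimulus_id,
                        row.dimension,
                        row.factor,
                        exc,
                    )
            records.append(rec)

        n_runnable = int((~tests["excluded_for_reliability"]).sum())
        if n_runnable and n_failed / n_runnable > max_failure_fraction:
            raise BatteryError(
                f"{n_failed}/{n_runnable} tests failed (> {max_failure_fraction:.0%})"
            )

        table = pd.DataFrame(records, columns=BATTERY_COLUMNS)

        # BH within families, over tests that actually produced a p-value
        ok = table["p_raw"].notna()
        if self.family == "global":
            families = [table.index[ok]]
        else:
            families = [
                idx[ok.loc[idx]]
                for _, idx in table.groupby("stimulus_id", sort=False).groups.items()
            ]
        for idx in families:
            if len(idx) == 0:
                continue
            p_adj, reject = bh_adjust(table.loc[idx, "p_raw"].to_numpy(), q=q)
            table.loc[idx, "p_adjusted"] = p_adj
            table.loc[idx, "significant"] = reject

        result = BatteryResult(
            table=table,
            config={
                "q": q,
                "n_boot": bootstrap.n_boot if bootstrap else n_boot,
                "family": self.family,
                "smoothing": {
                    "degree": self.smoothing.degree,
                    "kernel": self.smoothing.kernel,
                    "bandwidth": self.smoothing.bandwidth,
                },
                "reliability_threshold": self.reliability_threshold,
            },
            seed=seed,
        )
        out = BatteryResults(result=result)
        logger.info(
            "battery done: %d/%d significant (%.1f%%)",
            out.n_significant,
            int(ok.sum()),
            100 * out.fraction_significant,
        )
        return out


def run_battery(
    dataset: StudyDataset,
    factors,
    smoothing: SmoothingSpec | None = None,
    bootstrap: BootstrapSpec | None = None,
    q: float = 0.05,
    master_seed=0,
    **kwargs,
) -> BatteryResults:
    """Functional wrapper: build the battery model and fit it."""
    model = EmotionRatingBattery(dataset, factors, smoothing=smoothing, **kwargs)
    return model.fit(q=q, bootstrap=bootstrap, seed=master_seed)


def render_significance_matrix(results: BatteryResults, fig_path, tsv_path):
    """Write the factor x (stimulus, dimension) significance figure and TSV."""
    results.plot_significance(fig_path=fig_path, tsv_path=tsv_path)
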