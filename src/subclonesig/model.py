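"""Top-level model interface.

:class:`SubcloneExperiment` bundles a catalog and a lineage manifest and,
on :meth:`~SubcloneExperiment.fit`, runs the full analytical cascade for
every experimental condition against the controls:

1. background model from the control subclones (averaged burden/profile);
2. burden excess test (bootstrap null + permutation p-value, with
   Benjamini–Hochberg adjustment across conditions);
3. signal-to-noise ratio of the spectra;
4. bootstrap background subtraction to the experiment-associated
   signature;
5. per-subclone subtraction and cosine stability of the signature.

The returned :class:`SubcloneExperimentResults` carries estimates,
uncertainties and diagnostics, renders a text ``summary()`` and converts
to tidy frames for export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .catalog import Catalog, SignatureProfile
from .errors import MissingControlsError
from .qc import LineageManifest
from .stats import (
    BurdenTestResult,
    ProfileStats,
    SNRResult,
    StabilityReport,
    bh_adjust,
    burden_test,
    profile_stats,
    snr,
    stability_report,
)
from .subtraction import (
    BackgroundModel,
    SubtractionResult,
    fit_background,
    subtract_background,
)


@dataclass
class ConditionResult:
    """Everything computed for one experimental condition vs the controls."""

    condition: str
    samples: List[str]
    burden: BurdenTestResult
    p_adjusted: float
    snr: SNRResult
    subtraction: SubtractionResult
    stability: Optional[StabilityReport]
    exp_stats: ProfileStats


class SubcloneExperiment:
    """Signature-discovery model for one subclone experiment.

    Parameters
    ----------
    catalog : Catalog
        Channels x samples counts for one mutation class, covering the
        manifest's subclones.
    manifest : LineageManifest
        Declared lineage and control/experimental condition labels.
    """

    def __init__(self, catalog: Catalog, manifest: LineageManifest):
        self.catalog = catalog
        self.manifest = manifest
        controls = [s for s in manifest.control_samples() if s in catalog.samples]
        if len(controls) < 2:
            raise MissingControlsError(
                "experiment needs >= 2 control subclones present in the catalog"
            )
        self.controls = controls

    @classmethod
    def from_files(cls, catalog_tsv: str, manifest_yaml: str, scheme=None):
        """Build from a catalog TSV and a manifest YAML (SBS-96 by default)."""
        from .channels import sbs96_scheme
        from .io import read_catalog, read_manifest

        scheme = scheme or sbs96_scheme()
        return cls(read_catalog(catalog_tsv, scheme), read_manifest(manifest_yaml))

    def fit(
        self,
        n_boot: int = 2000,
        seed: int = 0,
        p_cutoff: float = 0.01,
        stability_cutoff: float = 0.9,
        alternative: str = "greater",
    ) -> "SubcloneExperimentResults":
        """Run the full control-vs-experimental cascade for every condition."""
        background = fit_background(self.catalog.subset(self.controls))
        ctrl_stats = profile_stats(self.catalog, self.controls)
        ctrl_burdens = self.catalog.subset(self.controls).burdens()

        conditions: Dict[str, ConditionResult] = {}
        raw_p: List[float] = []
        for k, name in enumerate(self.manifest.conditions()):
            samples = [
                s
                for s in self.manifest.experimental_samples(name)
                if s in self.catalog.samples
            ]
            if not samples:
                continue
            sub_catalog = self.catalog.subset(samples)
            bt = burden_test(
                ctrl_burdens.to_numpy(),
                sub_catalog.burdens().to_numpy(),
                n_boot=n_boot,
                seed=seed + k,
                alternative=alternative,
                p_cutoff=p_cutoff,
            )
            exp_stats = profile_stats(self.catalog, samples)
            ratio = snr(ctrl_stats, exp_stats)
            subtraction = subtract_background(
                sub_catalog, background, n_boot=n_boot, seed=seed + 1000 + k
            )
            stability = None
            if len(samples) >= 2:
                per_sub: List[SignatureProfile] = []
                ok = True
                for j, s in enumerate(samples):
                    res = subtract_background(
                        self.catalog.subset([s]),
                        background,
                        n_boot=n_boot,
                        seed=seed + 2000 + 17 * k + j,
                    )
                    if res.signature.is_empty:
                        ok = False
                        break
                    per_sub.append(res.signature)
                if ok:
                    stability = stability_report(per_sub, cutoff=stability_cutoff)
            conditions[name] = ConditionResult(
                condition=name,
                samples=samples,
                burden=bt,
                p_adjusted=np.nan,
                snr=ratio,
                subtraction=subtraction,
                stability=stability,
                exp_stats=exp_stats,
            )
            raw_p.append(bt.p_value)
        if conditions:
            adj = bh_adjust(raw_p)
            for res, q in zip(conditions.values(), adj):
                res.p_adjusted = float(q)
        return SubcloneExperimentResults(
            model=self,
            background=background,
            control_stats=ctrl_stats,
            conditions=conditions,
            n_boot=n_boot,
            seed=seed,
            p_cutoff=p_cutoff,
        )


@dataclass
class SubcloneExperimentResults:
    """Fitted results: background model plus per-condition statistics."""

    model: SubcloneExperiment
    background: BackgroundModel
    control_stats: ProfileStats
    conditions: Dict[str, ConditionResult]
    n_boot: int
    seed: int
    p_cutoff: float

    def condition_frame(self) -> pd.DataFrame:
        """One row per condition: burdens, p-values, SNR, stability."""
        rows = []
        for name, c in self.conditions.items():
            rows.append(
                {
                    "condition": name,
                    "n_subclones": len(c.samples),
                    "control_burden": c.burden.control_burden,
                    "experimental_burden": c.burden.observed_burden,
                    "p_value": c.burden.p_value,
                    "p_adjusted": c.p_adjusted,
                    "significant": c.burden.significant,
                    "snr": c.snr.snr,
                    "attributed_burden": c.subtraction.attributed_burden,
                    "background_scale": c.subtraction.background_scale,
                    "min_cosine": (
                        c.stability.min_cosine if c.stability else np.nan
                    ),
                    "stable": c.stability.stable if c.stability else None,
                }
            )
        return pd.DataFrame(rows)

    def signature(self, condition: str) -> SignatureProfile:
        return self.conditions[condition].subtraction.signature

    def plot_signature(self, condition: str, ax=None):
        """Bar plot of a condition's extracted signature."""
        from .plotting import plot_profile

        return plot_profile(
            self.signature(condition), ax=ax,
            title=f"{condition}: experiment-associated signature",
        )

    def summary(self) -> str:
        """Readable report of the fitted experiment."""
        lines = [
            "Subclone signature experiment",
            "=" * 64,
            f"scheme: {self.model.catalog.scheme.name}   "
            f"controls: {len(self.model.controls)}   "
            f"n_boot: {self.n_boot}   seed: {self.seed}",
            f"background burden: {self.background.burden:.1f} mutations/subclone",
            "",
        ]
        df = self.condition_frame()
        if df.empty:
            lines.append("no experimental conditions present")
        else:
            with pd.option_context("display.width", 120):
                lines.append(
                    df.round(
                        {
                            "control_burden": 1,
                            "experimental_burden": 1,
                            "p_value": 4,
                            "p_adjusted": 4,
                            "snr": 2,
                            "attributed_burden": 1,
                            "background_scale": 3,
                            "min_cosine": 3,
                        }
                    ).to_string(index=False)
                )
        for name, c in self.conditions.items():
            top = (
                c.subtraction.signature.to_series()
                .sort_values(ascending=False)
                .head(5)
            )
            lines += [
                "",
                f"[{name}] top signature channels: "
                + ", ".join(f"{ch} {w:.2f}" for ch, w in top.items()),
            ]
            if c.subtraction.zeroed_channels:
                lines.append(
                    f"[{name}] channels clamped to zero within their 99% CI: "
                    f"{len(c.subtraction.zeroed_channels)}"
                )
        return "\n".join(lines)
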