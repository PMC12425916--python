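"""Four-model scrutiny of a claimed prospective effect.

For each study the pipeline simulates standardized data matched to the
study's six correlations and sample size, fits the CLPM (A), the reversed
CLPM (B), the latent change score model (C) and the artifactualness model
(D), and classifies the claimed effect by sign convergence:

* consistent_with_genuine — A significant, the time-reversed effect B has
  the opposite sign, and the change-score effect C is significant with the
  same sign as A (all three expectations under a genuine effect hold);
* artifactual_pattern — A significant but B shares its sign, C is null or
  opposite-signed, and the no-direct-effect model D fits well;
* inconclusive — anything else (including the hedged borderline cases).

The rule operationalizes qualitative expectations; thresholds (alpha for
significance, the CFI cutoff for "fits well") are configurable and the
verdict deliberately speaks of a *pattern*, not proof.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ScrutinyError
from .models import (
    EffectEstimate,
    build_artifact_model,
    build_clpm,
    build_lcsm,
    build_reversed_clpm,
    focal_effect,
)
from .sem import FitIndices, SemModel, baseline_chi2, fit_indices
from .simulate import correlation_matrix, sample_mvn
from .studies import StudyRecord

__all__ = [
    "VerdictConfig",
    "ScrutinyResult",
    "classify_pattern",
    "scrutinize_study",
    "scrutinize_all",
]

logger = logging.getLogger(__name__)

CONSISTENT = "consistent_with_genuine"
ARTIFACTUAL = "artifactual_pattern"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class VerdictConfig:
    """Thresholds for the sign-convergence verdict."""

    alpha: float = 0.05
    cfi_good: float = 0.95
    rmsea_good: float = 0.06

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class ScrutinyResult:
    """Per-effect verdict bundle: focal effects A-C, model-D fit, classification."""

    effect_id: str
    effect_A: EffectEstimate
    effect_B: EffectEstimate
    effect_C: EffectEstimate
    fit_D: FitIndices
    verdict: str
    notes: str = ""


def _sign(x: float) -> int:
    return 1 if x >= 0 else -1


def classify_pattern(a: EffectEstimate, b: EffectEstimate, c: EffectEstimate,
                     d: FitIndices, config: VerdictConfig = VerdictConfig()) -> str:
    """Deterministic sign-convergence verdict from the four model outputs."""
    sa, sb, sc = _sign(a.b), _sign(b.b), _sign(c.b)
    if a.significant and sb == -sa and c.significant and sc == sa:
        return CONSISTENT
    if (a.significant and sb == sa
            and (not c.significant or sc == -sa)
            and d.cfi >= config.cfi_good):
        return ARTIFACTUAL
    return INCONCLUSIVE


def scrutinize_study(record: StudyRecord, mode: str = "exact", seed: int = 0,
                     config: VerdictConfig = VerdictConfig()) -> ScrutinyResult:
    """Run the four-model scrutiny for one study record.

    Builds the 4x4 correlation matrix from the record, simulates an
    n x 4 standardized dataset (exact or stochastic mode), fits models A-D,
    extracts standardized focal effects with Wald CIs, computes model-D fit
    indices against the independence baseline, and classifies.
    """
    notes: list[str] = []
    if record.n < 50:
        warnings.warn(
            f"effect {record.effect_id!r}: n={record.n} is small; "
            "scrutiny verdicts are unreliable below n=50",
            stacklevel=2,
        )
        notes.append(f"small sample (n={record.n})")
    try:
        target = correlation_matrix(record)
        data = sample_mvn(target, record.n, mode=mode, seed=seed)
        x = data.scores
        xc = x - x.mean(axis=0)
        s4 = xc.T @ xc / x.shape[0]
        n = record.n

        sign = 1 if record.r_p1e1 >= 0 else -1
        sign_w2 = 1 if record.r_p2e2 >= 0 else -1
        if sign != sign_w2:
            msg = (f"effect {record.effect_id!r}: wave-1 and wave-2 cross "
                   f"correlations disagree in sign; using wave 1 ({sign:+d})")
            logger.warning(msg)
            notes.append("cross-correlation sign disagreement between waves")

        def fit(spec, s, label):
            model = SemModel(spec).fit_moments(s, n)
            logger.debug(
                "effect %s: %s converged=%s iter=%d chi2=%.4g",
                record.effect_id, label, model.converged_, model.n_iter_, model.chi2_,
            )
            return model.to_semfit()

        fit_a = fit(build_clpm(), s4, "A/clpm")
        idx3 = [0, 2, 3]  # (P1, E1, E2) block for the reversed model
        fit_b = fit(build_reversed_clpm(), s4[np.ix_(idx3, idx3)], "B/reversed")
        fit_c = fit(build_lcsm(), s4, "C/lcsm")
        fit_d = fit(build_artifact_model(sign), s4, "D/artifact")

        eff_a = focal_effect(fit_a, "clpm", alpha=config.alpha)
        eff_b = focal_effect(fit_b, "reversed", alpha=config.alpha)
        eff_c = focal_effect(fit_c, "lcsm", alpha=config.alpha)
        ind_d = fit_indices(fit_d, baseline_chi2(s4, n))
    except ScrutinyError as err:
        raise type(err)(f"effect {record.effect_id!r}: {err}") from err

    verdict = classify_pattern(eff_a, eff_b, eff_c, ind_d, config)
    return ScrutinyResult(
        effect_id=record.effect_id,
        effect_A=eff_a, effect_B=eff_b, effect_C=eff_c,
        fit_D=ind_d, verdict=verdict, notes="; ".join(notes),
    )


def scrutinize_all(records, mode: str = "exact", seed: int = 0,
                   config: VerdictConfig = VerdictConfig()) -> list[ScrutinyResult]:
    """Scrutinize a batch of records in input order.

    Per-record failures are logged and skipped (fault isolation); the batch
    never aborts because one record is invalid.  Verdict counts are logged
    at the end of the run.
    """
    records = list(records)
    if not records:
        logger.warning("scrutinize_all called with an empty record list")
        return []
    results: list[ScrutinyResult] = []
    failures: list[tuple[str, Exception]] = []
    for i, record in enumerate(records):
        rec_seed = (seed + 1_000_003 * i) % (2 ** 31)
        try:
            results.append(scrutinize_study(record, mode=mode, seed=rec_seed,
                                            config=config))
        except ScrutinyError as err:
            logger.error("skipping effect %r: %s", record.effect_id, err)
            failures.append((record.effect_id, err))
    counts: dict[str, int] = {}
    for r in results:
        counts[r.verdict] = counts.get(r.verdict, 0) + 1
    logger.info("scrutinized %d/%d effects; verdicts: %s; failures: %d",
                len(results), len(records), counts, len(failures))
    return results
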