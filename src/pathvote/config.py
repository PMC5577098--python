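"""Run-level configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .containers import DataError

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of the full pipeline with their conventional defaults.

    alpha
        Raw p-value cutoff of the DE screen (0.05).
    top_n
        Number of accuracy-ranked DE pathways entering selection (35).
    theta
        Diversity threshold below which a classifier pair is considered
        redundant (0.15).
    n_runs, n_folds
        Repeated balanced CV protocol (100 x 5).
    kernel
        Base SVM kernel, ``rbf`` or ``linear``.
    min_prefix
        Smallest prefix size evaluated during the preliminary optimisation.
    de_method
        ``moderated`` (empirical-Bayes t) or ``welch``.
    adjust_p
        Apply Benjamini-Hochberg before the alpha cutoff (off by default).
    seed
        Master seed; every stage derives its own stream from it.
    """

    alpha: float = 0.05
    top_n: int = 35
    theta: float = 0.15
    n_runs: int = 100
    n_folds: int = 5
    kernel: str = "rbf"
    min_prefix: int = 1
    de_method: str = "moderated"
    adjust_p: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise DataError("alpha must be in (0, 1)")
        if self.top_n < 1:
            raise DataError("top_n must be >= 1")
        if not (0 <= self.theta <= 1):
            raise DataError("theta must lie in [0, 1]")
        if self.kernel not in ("rbf", "linear"):
            raise DataError(f"unsupported kernel {self.kernel!r}")
        if self.min_prefix < 1:
            raise DataError("min_prefix must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
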