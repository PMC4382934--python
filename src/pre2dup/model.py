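"""Model-object surface over the period-construction pipeline.

:class:`Pre2Dup` binds a purchase stream, institutional stays and a
parameter space; :meth:`Pre2Dup.fit` runs the iterated decision
procedure and returns a :class:`Pre2DupResults` carrying the periods,
the learned refill-length modes, convergence diagnostics and a
summary table.
"""

from __future__ import annotations

import datetime as dt
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io as _io
from .core import DrugUsePeriod, PipelineResult, run_pipeline
from .parameters import ParameterSpace
from .refill import build_refill_distributions
from .synthetic import GroundTruth, score_against_truth

__all__ = ["Pre2Dup", "Pre2DupResults"]


class Pre2Dup:
    """Drug-use-period construction model for a dispensing cohort.

    Parameters
    ----------
    purchases
        Dispensing records (:class:`~pre2dup.io.Purchase`). Harmonised
        on entry when a ``code_map`` is given; rows without an ATC code
        go to the exceptions sink either way.
    stays
        Institutional stays; merged per person internally.
    params
        The expert :class:`~pre2dup.parameters.ParameterSpace`;
        defaults to global constants with empty ATC/vnr tables.
    code_map
        Optional ATC-rename / DDD-fill corrections.
    """

    def __init__(
        self,
        purchases: Iterable[_io.Purchase],
        stays: Iterable[_io.InstitutionalStay] | None = None,
        params: ParameterSpace | None = None,
        code_map: _io.CodeMap | None = None,
    ):
        kept, exceptions = _io.harmonize(purchases, code_map)
        self.purchases: list[_io.Purchase] = kept
        self.exceptions: list[_io.ExceptionRecord] = exceptions
        self.stays: list[_io.InstitutionalStay] = list(stays or [])
        self.params: ParameterSpace = params or ParameterSpace()

    @classmethod
    def from_dataframes(
        cls,
        purchases: pd.DataFrame,
        stays: pd.DataFrame | None = None,
        params: ParameterSpace | None = None,
        code_map: _io.CodeMap | None = None,
        column_map: Mapping[str, str] | None = None,
    ) -> "Pre2Dup":
        """Build the model from in-memory tables.

        ``column_map`` maps the standard column names
        (:data:`pre2dup.io.PURCHASE_COLUMNS`) onto the frame's columns.
        """
        import io as _stdio

        buf = _stdio.StringIO()
        purchases.to_csv(buf, index=False)
        buf.seek(0)
        recs = _io.read_purchases(buf, schema=column_map)
        stay_recs: list[_io.InstitutionalStay] = []
        if stays is not None and len(stays):
            sbuf = _stdio.StringIO()
            stays.to_csv(sbuf, index=False)
            sbuf.seek(0)
            stay_recs = _io.read_stays(sbuf, schema=column_map)
        return cls(recs, stay_recs, params=params, code_map=code_map)

    @classmethod
    def from_files(
        cls,
        purchases: str,
        stays: str | None = None,
        params: ParameterSpace | None = None,
        code_map: _io.CodeMap | None = None,
        column_map: Mapping[str, str] | None = None,
        sep: str = ",",
    ) -> "Pre2Dup":
        recs = _io.read_purchases(purchases, schema=column_map, sep=sep)
        stay_recs = _io.read_stays(stays, schema=column_map, sep=sep) if stays else []
        return cls(recs, stay_recs, params=params, code_map=code_map)

    def fit(
        self,
        max_iter: int = 5,
        initial_modes: Mapping[str, int] | None = None,
    ) -> "Pre2DupResults":
        """Run the iterated construction and return the results object."""
        result = run_pipeline(
            self.purchases,
            self.stays,
            self.params,
            max_iter=max_iter,
            initial_modes=initial_modes,
        )
        return Pre2DupResults(self, result)


class Pre2DupResults:
    """Fitted drug use periods with diagnostics.

    Attributes
    ----------
    periods : list of DrugUsePeriod
    modes : dict
        Learned vnr → typical refill length (days).
    n_iterations : int
    converged : bool
    """

    def __init__(self, model: Pre2Dup, result: PipelineResult):
        self.model = model
        self.periods: list[DrugUsePeriod] = sorted(
            result.periods, key=lambda p: (p.person_id, p.atc, p.start)
        )
        self.modes: dict[str, int] = result.modes
        self.n_iterations: int = result.n_iterations
        self.converged: bool = result.converged

    @property
    def periods_frame(self) -> pd.DataFrame:
        """The eight-field period table as a DataFrame."""
        return pd.DataFrame(
            [
                {
                    "start_date": p.start,
                    "end_date": p.end,
                    "person_id": p.person_id,
                    "atc": p.atc,
                    "total_ddd": p.total_ddd,
                    "hospital_days": p.hospital_days,
                    "n_purchases": p.n_purchases,
                    "mean_ddd_per_day": p.mean_ddd_per_day,
                }
                for p in self.periods
            ],
            columns=list(_io.PERIOD_COLUMNS),
        )

    def refill_distributions(self):
        """Per-package refill-length distributions of the fitted periods."""
        return build_refill_distributions(
            self.periods, self.model.params.global_params
        )

    def save_periods(self, path, sep: str = ",") -> None:
        _io.write_periods(self.periods, path, sep=sep)

    def save_exceptions(self, path, sep: str = ",") -> None:
        _io.write_exceptions(self.model.exceptions, path, sep=sep)

    def score(self, truth: GroundTruth) -> dict:
        """Error report against a synthetic cohort's ground truth."""
        return score_against_truth(self.periods, truth)

    def summary(self) -> str:
        """Cohort overview per anatomical main group (ATC 1st level)."""
        df = self.periods_frame
        lines = [
            "Drug use period construction",
            "=" * 64,
            f"purchases used     : {len(self.model.purchases)}",
            f"exception rows     : {len(self.model.exceptions)}",
            f"periods            : {len(self.periods)}",
            f"iterations         : {self.n_iterations}"
            + ("" if self.converged else "  (not converged)"),
            f"learned modes      : {len(self.modes)} packages",
            "",
        ]
        if len(df):
            df = df.assign(
                atc1=df["atc"].str[0],
                length_days=(
                    pd.to_datetime(df["end_date"]) - pd.to_datetime(df["start_date"])
                ).dt.days,
            )
            agg = (
                df.groupby("atc1")
                .agg(
                    periods=("atc", "size"),
                    median_len=("length_days", "median"),
                    mean_len=("length_days", "mean"),
                    median_dose=("mean_ddd_per_day", "median"),
                )
                .reset_index()
            )
            lines.append(
                f"{'ATC':<4}{'periods':>8}{'median d':>10}{'mean d':>9}{'med DDD/d':>11}"
            )
            lines.append("-" * 42)
            for r in agg.itertuples(index=False):
                lines.append(
                    f"{r.atc1:<4}{r.periods:>8}{r.median_len:>10.0f}"
                    f"{r.mean_len:>9.1f}{r.median_dose:>11.2f}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<Pre2DupResults: {len(self.periods)} periods, "
            f"{self.n_iterations} iterations, converged={self.converged}>"
        )
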