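"""End-to-end orchestration: generate -> cost -> DID -> sensitivity ->
payment model -> WTP, with a manifest recording configuration and versions.

Every stage writes CSV that the next stage re-reads, so the pipeline is
restartable from any intermediate file, and two runs with the same seed
produce byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortParams, generate_cohort, generate_delivery_components, generate_wtp
from .config import UnitCostConfig
from .costing import aggregate_costs, write_cost_lines
from .did import TestFamily, did_table
from .errors import ParameterError
from .payment import payment_table, wtp_summary, copay_feasibility, CostShareParams, CATEGORY_LIMITS, CATEGORY_SHARE_RATES
from .sensitivity import tornado

log = logging.getLogger("copecba")


@dataclass
class RunConfig:
    out_dir: str = "cba_output"
    seed: int = 7
    n_cope: int = 130
    n_usual: int = 120
    bootstrap: int = 10_000
    family_size: int = 18
    alpha: float = 0.05
    external_call_fraction: float = 1.0
    wtp_threshold: float = 25.0
    payment_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0 or self.bootstrap < 1:
            raise ParameterError("seed must be >= 0 and bootstrap >= 1")


def _float_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


def run_full_pipeline(
    config: RunConfig, cost_config: UnitCostConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run every stage, writing each output under ``config.out_dir``.

    Returns the in-memory report bundle keyed by stage name.
    """
    cost_config = cost_config or UnitCostConfig.default()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("generating synthetic cohort (seed=%d)", config.seed)
    params = CohortParams(n_cope=config.n_cope, n_usual=config.n_usual,
                          seed=config.seed)
    dyads, records = generate_cohort(params)
    wtp = generate_wtp(params, dyads)
    components = generate_delivery_components(params, cost_config)
    _float_csv(dyads, out / "dyads.csv")
    _float_csv(records, out / "utilization.csv")
    _float_csv(wtp, out / "wtp.csv")
    _float_csv(components, out / "delivery_components.csv")

    log.info("costing %d utilization records", len(records))
    cost_lines = aggregate_costs(records, cost_config)
    write_cost_lines(cost_lines, out / "cost_lines.csv")

    log.info("DID analysis (B=%d)", config.bootstrap)
    family = TestFamily(n_tests=config.family_size, alpha=config.alpha)
    table2 = did_table(cost_lines, family=family, B=config.bootstrap,
                       seed=config.seed)
    _float_csv(table2, out / "did_table.csv")

    log.info("sensitivity scenarios")
    tornado_df = tornado(components,
                         external_call_fraction=config.external_call_fraction)
    _float_csv(tornado_df, out / "tornado.csv")

    log.info("payment model")
    table3 = payment_table(**config.payment_overrides)
    table3.to_csv(out / "payment_model.csv", index=False)  # display-rounded

    median, fractions = wtp_summary(wtp, threshold=config.wtp_threshold)
    share_rows = []
    for cat in (2, 3):
        copay_per_session = 25.0 if CATEGORY_SHARE_RATES[cat] > 0 else 0.0
        cs = CostShareParams(share_rate=CATEGORY_SHARE_RATES[cat],
                             copay_per_session=copay_per_session,
                             sessions_per_month=3)
        copay, feasible = copay_feasibility(cs, CATEGORY_LIMITS[cat])
        share_rows.append({
            "chcpe_category": cat,
            "median_wtp": median,
            "fraction_wtp_ge_threshold": fractions.get(cat, float("nan")),
            "monthly_copay": copay,
            "copay_feasible": feasible,
        })
    wtp_report = pd.DataFrame(share_rows)
    _float_csv(wtp_report, out / "wtp_summary.csv")

    manifest = {
        "package": "copecba",
        "version": __version__,
        "run_config": asdict(config),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return {
        "dyads": dyads, "records": records, "wtp": wtp,
        "components": components, "cost_lines": cost_lines,
        "did_table": table2, "tornado": tornado_df,
        "payment_model": table3, "wtp_summary": wtp_report,
    }
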