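"""Helper: degenerate stage fits whose coefficient draws are all zero except
a shared intercept, so predicted beliefs are identical at every stage."""

import numpy as np
import pandas as pd

import bayesurp as bs
from bayesurp.stage_models import STAGES, build_stage_spec, encode_design


def constant_fits(intercept: float, n_draws: int = 40) -> dict[str, bs.PosteriorFit]:
    record = list(bs.fixture_item().records.values())[0]
    frame = pd.DataFrame([record.to_row()])
    fits = {}
    for stage in STAGES:
        spec = build_stage_spec(stage)
        _, cols, stats = encode_design(frame, spec)
        dim = len(cols) + 2  # + one genre deviation + log re-sd
        draws = np.zeros((2, n_draws, dim))
        draws[:, :, 0] = intercept
        draws[:, :, -1] = np.log(0.3)
        fits[stage] = bs.PosteriorFit(
            spec=spec, priors=bs.PriorConfig(), draws=draws,
            param_names=cols + ["genre_z[g0]", "log_tau[0]"],
            design_info={"columns": cols, "length_stats": stats,
                         "genre_levels": ["g0"]},
            diagnostics={})
    return fits
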