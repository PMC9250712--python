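import numpy as np

from seascord import ProportionSeries


def make_series(values, series_id="s", start_year=2015):
    return ProportionSeries(
        series_id=series_id, start_year=start_year, start_month=1,
        values=np.asarray(values, dtype=float),
    )
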