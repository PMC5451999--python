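import numpy as np

from pm25ens.data_model import LocalProjection, MeasurementPanel, Station


def make_log_panel(values: np.ndarray) -> MeasurementPanel:
    """Wrap a raw station × day matrix as a log-scale panel for tests."""
    proj = LocalProjection(117.0, 36.4)
    n_s, n_d = values.shape
    stations = [Station.from_lonlat(f"S{i:03d}", 117 + 0.01 * i,
                                    36 + 0.01 * i, proj)
                for i in range(n_s)]
    return MeasurementPanel(stations=stations, days=np.arange(1, n_d + 1),
                            values=values, scale="log", projection=proj)
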