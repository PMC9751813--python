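"""Small reference datasets bundled with the package.

``rice_longevity_panel`` carries published probit seed-longevity parameters
for a diversity panel of 20 rice (Oryza sativa) accessions experimentally
aged under elevated partial pressure of oxygen (EPPO, 20 MPa air at 35 °C),
both as fitted directly to the EPPO germination data and after the
replicate-wise pressure-control correction (ΔEPPO).  Columns follow the
conventional longevity-table layout: initial viability Ki (NED) with its
standard error, slope σ⁻¹ (NED/day) with its standard error, and P50 (days).
It is used for worked examples and as an input to panel-summary utilities.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["rice_longevity_panel"]

_RICE_PANEL_CSV = """\
accession,variety,treatment,Ki,se_Ki,sigma_inv,se_sigma_inv,P50
IRGC 117264,AZUCENA,EPPO,1.63,0.12,0.083,0.005,19.6
IRGC 117265,DOM SUFID,EPPO,2.18,0.18,0.079,0.007,27.4
IRGC 117266,DULAR,EPPO,1.42,0.11,0.069,0.005,20.7
IRGC 117267,FR 13 A,EPPO,3.97,0.50,0.123,0.015,32.2
IRGC 117268,IR 64-21,EPPO,1.58,0.11,0.068,0.005,23.5
IRGC 117269,LI JIANG XIN TUAN HEI GU,EPPO,1.30,0.11,0.077,0.005,16.9
IRGC 117270,M202,EPPO,1.45,0.11,0.098,0.006,14.7
IRGC 117271,MINGHUI 63,EPPO,1.64,0.12,0.086,0.006,19.1
IRGC 117272,MOROBEREKAN,EPPO,2.31,0.19,0.087,0.007,26.4
IRGC 117273,N 22,EPPO,1.12,0.09,0.064,0.004,17.5
IRGC 117274,NIPPONBARE,EPPO,0.70,0.09,0.080,0.006,8.8
IRGC 117275,POKKALI,EPPO,1.98,0.14,0.079,0.005,25.1
IRGC 117276,SADU CHO,EPPO,2.02,0.14,0.099,0.006,20.3
IRGC 117277,SANHUANGZHAN No 2,EPPO,1.58,0.09,0.064,0.003,24.7
IRGC 117278,SWARNA,EPPO,1.44,0.10,0.062,0.004,23.4
IRGC 117279,TAINUNG 67,EPPO,1.50,0.14,0.101,0.007,14.9
IRGC 117280,ZHENSHAN 97 B,EPPO,1.72,0.13,0.104,0.007,16.5
IRGC 117281,ASWINA,EPPO,2.72,0.19,0.096,0.006,28.4
IRGC 117282,CYPRESS,EPPO,1.70,0.15,0.119,0.009,14.3
IRGC 117283,RAYADA,EPPO,3.24,0.36,0.102,0.011,31.8
IRGC 117264,AZUCENA,dEPPO,1.60,0.12,0.073,0.005,21.8
IRGC 117265,DOM SUFID,dEPPO,2.25,0.18,0.083,0.006,27.3
IRGC 117266,DULAR,dEPPO,1.66,0.15,0.072,0.005,23.1
IRGC 117267,FR 13 A,dEPPO,0.89,0.11,0.041,0.004,21.7
IRGC 117268,IR 64-21,dEPPO,1.78,0.15,0.072,0.005,24.5
IRGC 117269,LI JIANG XIN TUAN HEI GU,dEPPO,1.25,0.12,0.050,0.004,25.2
IRGC 117270,M202,dEPPO,1.12,0.10,0.061,0.004,18.4
IRGC 117271,MINGHUI 63,dEPPO,2.05,0.15,0.092,0.006,22.2
IRGC 117272,MOROBEREKAN,dEPPO,1.73,0.15,0.068,0.005,25.6
IRGC 117273,N 22,dEPPO,1.29,0.10,0.050,0.003,25.6
IRGC 117274,NIPPONBARE,dEPPO,0.82,0.12,0.068,0.006,12.0
IRGC 117275,POKKALI,dEPPO,2.36,0.20,0.095,0.007,24.9
IRGC 117276,SADU CHO,dEPPO,1.78,0.13,0.078,0.005,22.7
IRGC 117277,SANHUANGZHAN No 2,dEPPO,1.83,0.15,0.070,0.005,25.9
IRGC 117278,SWARNA,dEPPO,1.59,0.12,0.070,0.004,22.7
IRGC 117279,TAINUNG 67,dEPPO,1.23,0.13,0.071,0.006,17.3
IRGC 117280,ZHENSHAN 97 B,dEPPO,1.73,0.16,0.086,0.007,20.2
IRGC 117281,ASWINA,dEPPO,2.34,0.19,0.089,0.007,26.3
IRGC 117282,CYPRESS,dEPPO,1.26,0.13,0.071,0.006,17.9
IRGC 117283,RAYADA,dEPPO,3.10,0.27,0.097,0.008,31.8
"""


def rice_longevity_panel(treatment: str | None = None) -> pd.DataFrame:
    """Published longevity parameters for the 20-accession rice panel.

    Parameters
    ----------
    treatment
        ``"EPPO"`` or ``"dEPPO"`` to select one series, or ``None`` for
        both (long format, 40 rows).

    Returns
    -------
    DataFrame with columns ``accession, variety, treatment, Ki, se_Ki,
    sigma_inv, se_sigma_inv, P50``; ``p50`` is aliased for the summary
    utilities.
    """
    df = pd.read_csv(io.StringIO(_RICE_PANEL_CSV))
    df["p50"] = df["P50"]
    if treatment is not None:
        if treatment not in set(df["treatment"]):
            raise ValueError(f"unknown treatment {treatment!r}")
        df = df[df["treatment"] == treatment].reset_index(drop=True)
    return df
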