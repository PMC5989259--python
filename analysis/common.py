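"""Shared study definition for the numbered analysis drivers.

One synthetic three-population pooled study (two adapted lines plus a
control, 46 diploids per pool at ~35x) over a 1-Mb toy genome with 50
planted sweep loci in 5 genic blocks; half of the sweep genes also appear
in the differential-expression list, so the integration step has both
recoverable and expression-silent targets.
"""

from pathlib import Path

from poolscan.simulate import SimParams

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
STUDY_DIR = RESULTS / "study"
TABLES = RESULTS / "tables"
RUN_DIR = RESULTS / "run"

STUDY_PARAMS = SimParams(seed=1)  # defaults: see poolscan.simulate.SimParams


def require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise SystemExit(f"missing {path} — run {hint} first")
    return path
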