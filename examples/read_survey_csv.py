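"""Round-trip a survey panel through the long-format CSV dialect.

Shows the expected file layout (one row per colony and survey date), custom
column-name mapping, and how missing surveys are preserved.
"""

import tempfile
from pathlib import Path

import numpy as np

from whitepox import ScenarioConfig, generate_panel, read_panel, write_panel

panel, _ = generate_panel(
    ScenarioConfig(n_colonies=8, n_occasions=6, missing_rate=0.1), seed=2
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "survey.csv"
    write_panel(panel, path)
    print(Path(path).read_text().splitlines()[0])  # header
    loaded = read_panel(path)
    print(
        f"reloaded {loaded.n_colonies} colonies x {loaded.n_occasions} occasions, "
        f"{loaded.n_missing} missing cells, identical: {loaded.equals(panel)}"
    )

    # the same file with project-specific column names
    schema = {"colony_id": "tag", "presence": "whitepox_present"}
    path2 = Path(tmp) / "survey_renamed.csv"
    write_panel(panel, path2, schema=schema)
    again = read_panel(path2, schema=schema)
    print(f"custom column names round-trip: {again.equals(panel)}")
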