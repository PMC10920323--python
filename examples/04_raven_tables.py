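"""Parse a Raven Pro selection table.

Raven exports one row per selection per view, so the same bark often
appears twice (spectrogram and waveform view); the reader deduplicates
by selection id and sorts by onset.
"""

import tempfile
from pathlib import Path

from barkbeat import compute_iois, read_raven_selection_table

table = """Selection\tView\tChannel\tBegin Time (s)\tEnd Time (s)\tLow Freq (Hz)\tHigh Freq (Hz)
1\tSpectrogram 1\t1\t0.000\t0.110\t150\t2400
1\tWaveform 1\t1\t0.000\t0.110\t150\t2400
2\tSpectrogram 1\t1\t0.312\t0.428\t160\t2500
2\tWaveform 1\t1\t0.312\t0.428\t160\t2500
3\tSpectrogram 1\t1\t0.629\t0.741\t140\t2300
3\tWaveform 1\t1\t0.629\t0.741\t140\t2300
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "bout.txt"
    path.write_text(table)
    bout = read_raven_selection_table(path)

print(f"rows in table: 6, events after view dedup: {bout.n_events}")
print(f"onsets (s): {bout.onsets}")
print(f"IOIs (s):   {[round(x, 3) for x in compute_iois(bout).iois]}")
print(f"extra Raven columns kept: {sorted(bout.extra['raven_columns'])}")
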