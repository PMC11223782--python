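"""Label interface hot spots from a per-residue ddG table.

Reads an alanine-scan-style table of free-energy changes (kcal/mol) and
applies the band classification: >= 1.5 critical hot spot, [0.5, 1.5)
warm hot spot, below 0.5 (including stabilizing, negative values) none.
"""
from pathlib import Path

from pie import fixtures
from pie.hotspots import label_records, parse_ddg_table

work = Path("scratch_example")
work.mkdir(exist_ok=True)
ddg_path = work / "ddg.tsv"
ddg_path.write_text(fixtures.make_ddg_table(seed=0))

records = label_records(parse_ddg_table(ddg_path))
for r in records:
    print(f"{r.chain_id} {r.res_name}{r.res_num:<4d} "
          f"ddG = {r.ddg:+5.2f} kcal/mol  ->  {r.label.value}")

counts = {}
for r in records:
    counts[r.label.value] = counts.get(r.label.value, 0) + 1
print(f"\ncounts: {counts}")
print("CRITICAL residues are predicted to be essential for the "
      "interface; WARM ones contribute measurably.")
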