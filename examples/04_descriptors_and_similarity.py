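"""Descriptor vectors and the Pocket Similarity Index.

Detects pockets in four groove complexes, assembles the 109-descriptor
table, runs the prune -> standardize -> Euclidean distance -> Gaussian
kernel pipeline, and prints the nearest neighbors of one pocket.
"""
from pathlib import Path

from pie import fixtures
from pie.pipeline import ManifestEntry, PipelineConfig, run_pipeline
from pie.similarity import nearest_neighbors

work = Path("scratch_example")
work.mkdir(exist_ok=True)
entries = []
for seed, mode in [(1, "HD"), (2, "HD"), (3, "PL"), (4, "PL")]:
    sid = f"{mode.lower()}{seed}"
    path = work / f"{sid}.pdb"
    jitter = 0.15 if seed % 2 == 0 else 0.0
    path.write_text(fixtures.make_groove_complex(seed=seed, mode=mode,
                                                 jitter=jitter))
    entries.append(ManifestEntry(
        path=str(path), mode=mode, structure_id=sid,
        shared_accession="FIXA" if mode == "PL" else "",
        hd_id="hd1" if mode == "PL" else ""))

result = run_pipeline(entries, PipelineConfig())
table = result["descriptors"]
numeric = table.drop(columns=["structure_id", "source", "pocket_class"])
print(f"descriptor table: {numeric.shape[0]} pockets x "
      f"{numeric.shape[1]} descriptors")
print(f"columns dropped by the >95% non-zero rule: "
      f"{len(result['report'].descriptor_columns_dropped)}")
print(f"sigma (std of pairwise distances): {result['distances'].sigma:.4f}")

query = result['psi'].ids[0]
print(f"\nnearest neighbors of {query} (PSI, 1 = identical descriptors):")
for pid, value in nearest_neighbors(result["psi"], query,
                                    k=len(result["psi"].ids) - 1):
    print(f"  {pid:12s} PSI = {value:.4f}")
print("\nPSI = exp(-d^2 / 2 sigma^2) on standardized descriptor distance d.")
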