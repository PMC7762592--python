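# capsidkit

Predicting icosahedral capsid architectures of tailed phages from genome
length, with generalized Caspar–Klug lattice theory and 3D cage-mesh
generation.

## The problem

Tailed phages (*Duplodnaviria*, HK97-fold major capsid protein) build
icosahedral shells indexed by the triangulation number
*T*₀(*h*, *k*) = *h*² + *hk* + *k*², with 60 *T*₀ major capsid proteins
(MCPs) per shell. Beyond the familiar hexagonal lattice, capsid proteins can
organise on three further Archimedean tilings — trihexagonal, snub hexagonal
and rhombitrihexagonal — whose minor polygons host minor capsid proteins. At
conserved MCP size each tiling inflates the shell surface by a constant
factor αᵢ (1, 4/3, 7/3, 4/3 + 2√3/3 ≈ 2.488), giving the **generalized
T-number** *T*ᵢ = αᵢ·*T*₀ and the architecture series
*T* = 1, 1.33, 2.33, 2.49, 3, 4, …

No tailed phage has ever been imaged with *T* ≤ 3, yet two conserved
structural facts let genome length predict the architecture. Tailed phages
pack dsDNA at a nearly constant density (~0.5 bp/nm³), so genome length *G*
scales with shell volume (*G* ∝ *D*³); and the exposed surface per MCP is
nearly constant, so *T* scales with shell surface (*T* ∝ *D*²). Together
these force the allometric laws

        G(T) = a_G · T^{3/2}        D(T) = a_D · T^{1/2}

Fitted on log₁₀ scales to per-architecture averages of high-resolution
cryo-EM capsids, the published parameters are log₁₀ a_G = 0.37 ± 0.10,
b_G = 1.47 ± 0.09 (kbp) and log₁₀ a_D = 1.38 ± 0.34, b_D = 0.52 ± 0.03 (nm)
— statistically indistinguishable from the theoretical exponents 3/2 and
1/2. Any genome is then assigned the architecture whose model-mean genome
length is nearest, and genomes landing on *T* ≤ 4 are flagged as
small-capsid candidates worth structural follow-up.

`capsidkit` is for phage structural biologists and viromics researchers who
want to (a) scan genome collections for putative small-capsid phages,
(b) refit the allometric models to their own capsid measurement tables, and
(c) generate 3D cage meshes of any architecture on any of the four lattices
(including the dual Laves lattices) for visualisation or fitting.

## Worked example

```python
from capsidkit import (printed_fit, assign_t, default_t_grid,
                       generalized_t, build_cage, face_census)

fit = printed_fit("genome_kbp")     # G(T) = 10^0.37 * T^1.47
series = default_t_grid()           # deduplicated generalized grid, T < 40
for name, bp in [("Salmonella phage astrithr", 11600),
                 ("Mycoplasma virus P1", 11700),
                 ("OLNE01004159.1", 7400),
                 ("phiCrAss001", 102000)]:
    a = assign_t(bp, fit, series)
    flag = " (small-capsid candidate)" if a.is_small_candidate else ""
    print(f"{name:26s} {bp/1000:6.1f} kbp -> T = {a.assigned_t:.4g} "
          f"(model mean {a.nearest_mean_kbp:.2f} kbp){flag}")

arch = generalized_t(1, 1, "hexagonal")            # T = 3
mesh = build_cage(arch, sphericity=0.3, radius=21.4)
print(f"T = {arch.t:g} cage ({arch.mcp_count} MCPs): "
      f"V={mesh.n_vertices} E={mesh.n_edges} F={mesh.n_faces} {face_census(mesh)}")
```

prints

```
Salmonella phage astrithr    11.6 kbp -> T = 3 (model mean 11.79 kbp) (small-capsid candidate)
Mycoplasma virus P1          11.7 kbp -> T = 3 (model mean 11.79 kbp) (small-capsid candidate)
OLNE01004159.1                7.4 kbp -> T = 2.333 (model mean 8.15 kbp) (small-capsid candidate)
phiCrAss001                 102.0 kbp -> T = 13 (model mean 101.74 kbp)

T = 3 cage (180 MCPs): V=60 E=90 F=32 {'pentagon': 12, 'hexagon': 20}
```

The 11.6 and 11.7 kbp genomes sit essentially on the model mean for *T* = 3
(11.79 kbp); the 7.4 kbp gut contig lands on the snub-hexagonal *T* = 7/3
architecture; the 102 kbp crAssphage-sized genome maps to a conventional
*T* = 13 shell. The *T* = 3 cage is the truncated icosahedron: 12 pentamers
(at the five-fold vertices) plus 20 hexamers, i.e. 10 *T* + 2 capsomers, at
30% polyhedron-to-sphere interpolation and a 21.4 nm radius.

## Command line

```sh
capsidkit cage --h 2 --k 1 --lattice hex --sphericity 0.3 --radius 30 --format obj --out cage.obj
capsidkit simulate genomes --preset gut --n 1500 --seed 1 --out genomes.tsv
capsidkit predict --in genomes.tsv --params printed --out report/
capsidkit simulate capsids --seed 1 --noise 0.05 --out table.csv
capsidkit fit --table table.csv --variable genome --out fit.json
capsidkit metrics --table table.csv --out metrics/
```

`predict` accepts FASTA (plain or gzip) or two-column (id, length) tables
and writes per-genome assignments, a T-number frequency table and a JSON
small-candidate report; every run logs its parameters to `run_log.json`.

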