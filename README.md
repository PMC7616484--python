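# imflow

A headless, modular image- and object-analysis workflow engine for
multidimensional microscopy data.

Automated bioimage analysis pipelines are usually a fixed sequence of steps —
load an image, segment it, measure the detected objects, filter them, export
a spreadsheet. `imflow` represents such a pipeline as an ordered list of
**modules** operating on a per-job **workspace** of named images and object
sets, so the same workflow document runs unattended over a single file or a
whole folder of TIFFs. It is aimed at facility staff and analysts who need
reproducible batch quantification (cell/nucleus segmentation and counting,
particle tracking, skeleton/network morphometry) without a GUI or bespoke
scripting per experiment.

## What's inside

- **Interchangeable coordinate stores.** An identified object is a set of
  foreground voxels. It can be held as a *pointlist* (explicit (x, y, z)
  triples, 3 memory units per voxel), a per-slice *quadtree*, or a 3D
  *octree* (recursive subdivision into quadrants/octants that stops at
  uniformly foreground or background nodes, 4 units per node). All three
  satisfy one contract — membership, count, iteration, mask round-trip — so
  measurements are bit-identical whichever store is used; only memory
  differs. A single pixel in a 2^k square costs the quadtree 4k+1 nodes,
  while a large solid ellipse compresses by more than an order of magnitude
  relative to its pointlist.
- **Object relationships.** Parent-child (one-to-many; at most one parent per
  parent class, multiple parents across classes, grandparent chains) and
  symmetric partner (many-to-many) links, kept bidirectionally consistent and
  acyclic at all times. Tracks are coordinate-less parent objects over their
  per-frame detections; skeleton edges partner with the junctions they touch.
- **Workflow engine.** Reactive enablement (disabling a module automatically
  disables downstream modules whose input chains break), conditional
  skip/terminate modules, per-parameter visibility flags for a simplified
  end-user view, and canonical JSON serialization (`.wf.json`) whose round
  trip is byte-stable.
- **Modules.** TIFF load/save (5D, calibrated), Otsu/manual thresholding,
  hole filling, connected-component identification, shape measurement,
  measurement filters, linear-assignment frame-to-frame tracking with motion
  statistics (path length, displacement, directionality = displacement /
  path length, mean velocity), skeleton edge/junction decomposition with
  terminal-branch pruning, outline overlays, workspace housekeeping.
- **Batch + export.** Recursive job discovery with filename/folder/series
  filters, one isolated workspace per job, and xlsx export (one sheet per
  object class, optional per-image summary statistics) with the full
  serialized workflow embedded in a Configuration sheet — the exact pipeline
  behind any result file can be recovered and re-run from the file itself.
- **Synthetic fixtures.** Seeded generators for blob images, moving-spot
  movies, skeleton shapes and store-benchmark morphologies, each with ground
  truth; the entire test suite runs without external data.

## Worked example

Generate three synthetic nucleus images, write a workflow document, and run
the batch from the shell:

```python
from imflow import Workflow, create_module_spec, serialize_workflow
from imflow.synth import make_blob_image
from imflow.image_ops import save_image

for i in range(3):
    image, truth = make_blob_image(n_blobs=4, seed=i, extra_radii=(2.0,))
    save_image(image, f"demo/images/sample{i}.tif")

wf = Workflow()
wf.add(create_module_spec("load_image", nickname="Load image"))
wf.add(create_module_spec("apply_threshold", nickname="Apply threshold",
                          input="Raw", output="Binary"))
wf.add(create_module_spec("fill_holes", nickname="Fill holes", input="Binary"))
wf.add(create_module_spec("identify_objects", nickname="Identify objects",
                          input="Binary", output="Nuclei"))
wf.add(create_module_spec("measure_object_shape", input="Nuclei"))
wf.add(create_module_spec("filter_objects", input="Nuclei",
                          measurement="AREA_PX", predicate="<", threshold=50))
wf.add(create_module_spec("add_outline_overlay", input="Raw",
                          objects="Nuclei", output="Overlay"))
wf.add(create_module_spec("save_image", input="Overlay",
                          path="{stem}_overlay.tif"))
with open("demo/nuclei.wf.json", "w") as fh:
    fh.write(serialize_workflow(wf))
```

```console
$ imflow run --workflow demo/nuclei.wf.json --input demo/images --output demo/out --seed 7
jobs: 3  completed: 3  terminated: 0  failed: 0
exported: demo/out/results.xlsx
```

Each image contains four real nuclei plus one deliberately tiny blob; the
area filter (`AREA_PX < 50` removed) drops exactly the tiny one, so the
`Nuclei` sheet of `results.xlsx` holds 12 rows — 4 surviving nuclei per job —
with columns

```
Filename      Folder       Series  Object ID  Timepoint  AREA_CAL  AREA_PX ...
sample0.tif   demo/images          1          0          217       217
```

alongside an `Images` sheet (one row per job), a `Summary` sheet (per-image
mean/min/max/std/sum/count of every object measurement) and a
`Configuration` sheet holding the workflow verbatim. A colour overlay TIFF
per job lands in `demo/out`. `imflow validate --workflow …` checks a
document without running it, and `imflow describe --workflow …` prints the
module list with the end-user-visible parameters starred.

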