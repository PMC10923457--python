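"""Build the theatre mesh and inspect patches, then export to VTK.

The room is 8 x 6 x 3 m with a 2.4 x 2.6 m ceiling inlet, two 4 x 0.3 m
low wall outlets and a 1.8 x 0.8 x 0.8 m table; the incision (smoke
source) sits at (4, 3, 0.9) m.
"""

from theatresmoke import TheatreScene, build_mesh, locate_cell
from theatresmoke.scene import Patch
from theatresmoke.vtkio import write_vtk

scene = TheatreScene()
mesh = build_mesh(scene, (40, 30, 15))

print(f"cells: {mesh.n} = {mesh.n_cells} ({int((~mesh.fluid).sum())} solid)")
print(f"spacing: {mesh.d} m")
print(f"labelled inlet area : {mesh.patch_area(Patch.INLET):.2f} m^2 (target 6.24)")
print(f"labelled outlet area: {mesh.patch_area(Patch.OUTLET):.2f} m^2 "
      "(2 x 1.2 target; the 0.3 m slot height is a one-cell approximation here)")
print(f"incision cell: {locate_cell(mesh, scene.incision_point)}")

write_vtk("scratch_mesh.vtk", mesh, scalars={"fluid": mesh.fluid.astype(float)})
print("wrote scratch_mesh.vtk (legacy VTK structured points)")
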