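# Baseline "average mammalian cell" compartment table.
# membrane_potential_mV is interior minus immediate exterior
# (cytosol vs extracellular; mitochondria/lysosome vs cytosol).
# Total cell volume 4 pL: cytosol 89%, mitochondria 10%, lysosomes 1%.

[extracellular]
volume_L = 1.0e-6   # effectively unlimited reservoir
pH = 7.4
membrane_potential_mV = 0.0
lipid_fraction = 0.0

[cytosol]
volume_L = 3.56e-12
pH = 7.2
membrane_potential_mV = -60.0
lipid_fraction = 0.05
membrane_area_cm2 = 3.0e-5

[mitochondria]
volume_L = 4.0e-13
pH = 8.0
membrane_potential_mV = -160.0
lipid_fraction = 0.05
membrane_area_cm2 = 6.0e-5

[lysosome]
volume_L = 4.0e-14
pH = 5.0
membrane_potential_mV = 10.0
lipid_fraction = 0.05
membrane_area_cm2 = 1.0e-6
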