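# Molecular constants for the interfacial materials.
#   b:      coherent scattering length summed over non-labile atoms, fm
#   volume: molecular volume, Å^3
#   n_exch: labile (solvent-exchangeable) hydrogens per molecule
# Lipid volumes follow standard lipidomics tables (POPC head 331 / tails
# 925 Å^3; tetraoleoyl-cardiolipin head 530 / four-chain tails 1864 Å^3);
# substrate values from bulk densities.  All entries may be overridden by a
# user-supplied file of the same shape.

silicon:          # crystalline Si, V = atomic volume
  b: 4.1491
  volume: 20.02
  n_exch: 0

sio2:             # native oxide, amorphous, rho = 2.2 g/cm^3
  b: 15.755
  volume: 45.3
  n_exch: 0

popc_head:        # phosphocholine + glycerol + carbonyls, C10H18NO8P
  b: 60.07
  volume: 331.0
  n_exch: 0

popc_tail:        # palmitoyl + oleoyl hydrocarbon, C32H64
  b: -26.61
  volume: 925.0
  n_exch: 0

tocl_head:        # 2 phosphates + 3 glycerols + 4 carbonyls, C13H9O17P2 + 1 labile H
  b: 161.71
  volume: 530.0
  n_exch: 1

tocl_tail:        # four oleoyl chains, C68H132
  b: -41.49
  volume: 1864.0
  n_exch: 0
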