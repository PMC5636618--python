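# Synthetic reference sphere S-values for I-131 in unit-density water,
# computed by the deterministic chord-length quadrature model in
# scripts/make_sphere_reference.py (independent of the event-by-event
# Monte Carlo; see docs/methods.md). Not a published data product.
mass_g,s_gy_per_bq_s,provenance
0.1,2.772679e-10,chord_quadrature_v1
0.2,1.431113e-10,chord_quadrature_v1
0.5,5.922905e-11,chord_quadrature_v1
1.0,3.026710e-11,chord_quadrature_v1
2.0,1.543594e-11,chord_quadrature_v1
5.0,6.329977e-12,chord_quadrature_v1
10.0,3.226023e-12,chord_quadrature_v1
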