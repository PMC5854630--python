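name,cylinder_iol_plane_D,sphere_min_D,sphere_max_D,a_constant
SN6AT3,1.50,5.0,34.0,118.8
SN6AT4,2.25,5.0,34.0,118.8
SN6AT5,3.00,5.0,34.0,118.8
SN6AT6,3.75,5.0,34.0,118.8
SN6AT7,4.50,5.0,34.0,118.8
SN6AT8,5.25,5.0,34.0,118.8
SN6AT9,6.00,5.0,34.0,118.8
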