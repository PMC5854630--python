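name,cylinder_iol_plane_D,sphere_min_D,sphere_max_D,a_constant
ZCT100,1.00,5.0,34.0,118.8
ZCT150,1.50,5.0,34.0,118.8
ZCT225,2.25,5.0,34.0,118.8
ZCT300,3.00,5.0,34.0,118.8
ZCT400,4.00,5.0,34.0,118.8
ZCT450,4.50,5.0,34.0,118.8
ZCT525,5.25,5.0,34.0,118.8
ZCT600,6.00,5.0,34.0,118.8
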