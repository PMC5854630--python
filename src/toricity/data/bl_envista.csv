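name,cylinder_iol_plane_D,sphere_min_D,sphere_max_D,a_constant
MX60T125,1.25,5.0,34.0,116.5
MX60T200,2.00,5.0,34.0,116.5
MX60T275,2.75,5.0,34.0,116.5
MX60T350,3.50,5.0,34.0,116.5
MX60T425,4.25,5.0,34.0,116.5
MX60T500,5.00,5.0,34.0,116.5
MX60T575,5.75,5.0,34.0,116.5
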